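"""Seeded synthetic chemical libraries with planted structure-activity signal.

The generator emulates the conditions of a high-throughput steroidogenesis
screening campaign: a majority-inactive background of small drug-like /
pesticide-like molecules (~10% active prevalence) in which specific
substructure families — amino-triazines, phenols, aromatic primary amines,
benzidine-like diamines, phosphorodithioate esters and aryl halides — are
enriched among the active chemicals.

Structures are assembled by template-based string substitution over a
curated scaffold/substituent grammar, so every emitted SMILES is valid by
construction: each molecule is an alkyl backbone carrying one background
scaffold (alkyl chain, cyclohexane, benzene or pyridine core), zero or more
planted motif fragments, and random benign substituents.  Planted motifs may
occur in multiple copies on the same molecule (1 + Binomial(k, 0.5), k
configurable, default 3), the way real actives often carry repeated halide
or hydroxyl substitutions; with k = 0 the activity model is purely
set-based.

Activity is logistic in the planted motif instances: the log-odds of being
active are ``logit(active_rate) + sum(copies * log(odds_ratio))`` over the
planted motifs, after which the label may be flipped symmetrically with
probability ``label_noise``.  With no configured motif effects the active
fraction is exactly the base rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from rdkit import Chem

from .errors import ConfigurationError, PipelineError
from .records import ChemicalRecord, write_labels_csv, write_library_csv

# Appendable SMILES fragment templates; {r}/{s} are ring-closure slots filled
# with molecule-unique ring indices at assembly time.  Every fragment is
# attached inside a branch of the alkyl backbone, so fragments never bond to
# each other and each template's internal valences are final.
MOTIF_FRAGMENTS: dict[str, str] = {
    "triazine": "c{r}nc(SC)nc(OC)n{r}",
    "phenol": "c{r}cc(O)ccc{r}",
    "aromatic_amine": "c{r}cc(N)ccc{r}",
    "biphenyl_diamine": "c{r}c(N)ccc(-c{s}ccc(N)cc{s})c{r}",
    "phosphorodithioate": "SP(=S)(OC)OC",
    "aryl_halide": "c{r}cc(Cl)ccc{r}",
}

_SCAFFOLDS = (
    "CCCC",
    "CCC(C)C",
    "C{r}CCCCC{r}",   # cyclohexane
    "c{r}ccccc{r}",   # benzene
    "c{r}ccncc{r}",   # pyridine
)

# Benign substituents: none introduces an aromatic O-H, N-H, halide or other
# motif-defining feature, so planted motifs stay identifiable.
_SUBSTITUENTS = ("C", "CC", "CCC", "OC", "CCO", "C(=O)C", "C(C)C")




def motif_vocabulary() -> tuple[str, ...]:
    """Identifiers of the built-in planted-motif vocabulary."""
    return tuple(MOTIF_FRAGMENTS)


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic library.

    Parameters
    ----------
    n_chemicals:
        Library size (positive integer).
    active_rate:
        Baseline active probability for a motif-free chemical, in (0, 1).
        With no motif effects this is the expected overall active fraction.
    motif_effects:
        Mapping motif-id -> odds ratio (>= 1) applied per planted motif copy.
    label_noise:
        Probability in [0, 0.5) of symmetrically flipping the final label.
    seed:
        Integer seed; libraries are byte-identical given the same config.
    motif_prevalence:
        Probability in (0, 1) that each vocabulary motif is planted on a
        chemical, independently per motif.
    motif_extra_copies:
        Maximum number of extra copies of a planted motif; actual copies are
        1 + Binomial(motif_extra_copies, 0.5).  Zero gives the pure
        single-instance (set-based) activity model.
    endpoint:
        Name of the simulated activity endpoint.
    """

    n_chemicals: int
    active_rate: float = 0.10
    motif_effects: Mapping[str, float] = field(default_factory=dict)
    label_noise: float = 0.0
    seed: int = 0
    motif_prevalence: float = 0.25
    motif_extra_copies: int = 3
    endpoint: str = "E2up"

    def __post_init__(self) -> None:
        if not isinstance(self.n_chemicals, (int, np.integer)) or self.n_chemicals <= 0:
            raise ConfigurationError("n_chemicals must be a positive integer")
        if not 0.0 < self.active_rate < 1.0:
            raise ConfigurationError("active_rate must lie in (0, 1)")
        if not 0.0 <= self.label_noise < 0.5:
            raise ConfigurationError("label_noise must lie in [0, 0.5)")
        if not 0.0 < self.motif_prevalence < 1.0:
            raise ConfigurationError("motif_prevalence must lie in (0, 1)")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed must be an integer")
        if not isinstance(self.motif_extra_copies, (int, np.integer)) or self.motif_extra_copies < 0:
            raise ConfigurationError("motif_extra_copies must be a non-negative integer")
        for motif, odds_ratio in self.motif_effects.items():
            if motif not in MOTIF_FRAGMENTS:
                raise ConfigurationError(
                    f"motif_effects: unknown motif {motif!r}; "
                    f"known motifs are {sorted(MOTIF_FRAGMENTS)}"
                )
            if odds_ratio < 1.0:
                raise ConfigurationError(
                    f"motif_effects[{motif!r}] must be an odds ratio >= 1"
                )


@dataclass
class SyntheticLibrary:
    """Generated records plus the ground truth used to label them."""

    records: list[ChemicalRecord]
    truth: dict[str, dict]
    config: SyntheticConfig

    def __len__(self) -> int:
        return len(self.records)


def activity_probability(true_motifs: Mapping[str, int] | set, config: SyntheticConfig) -> float:
    """Active probability of a chemical given its planted motifs.

    ``true_motifs`` may be a set of motif ids (one copy each) or a mapping
    motif-id -> copy count.  Log-odds are additive per motif instance.
    """
    counts = (
        {m: 1 for m in true_motifs} if not isinstance(true_motifs, Mapping) else true_motifs
    )
    log_odds = math.log(config.active_rate / (1.0 - config.active_rate))
    for motif, copies in counts.items():
        log_odds += copies * math.log(config.motif_effects.get(motif, 1.0))
    return 1.0 / (1.0 + math.exp(-log_odds))


def assign_activity(
    true_motifs: Mapping[str, int] | set,
    config: SyntheticConfig,
    draw: float,
    noise_draw: float | None = None,
) -> str:
    """Label a chemical from its planted motifs and uniform deviates.

    The label is Bernoulli with the logistic probability of
    :func:`activity_probability`; if ``noise_draw`` is given the label is
    then flipped when ``noise_draw < config.label_noise``.
    """
    if not 0.0 <= draw < 1.0:
        raise ConfigurationError("draw must lie in [0, 1)")
    active = draw < activity_probability(true_motifs, config)
    if noise_draw is not None and noise_draw < config.label_noise:
        active = not active
    return "active" if active else "inactive"


def _fill_rings(template: str, counter: list[int]) -> str:
    out = template
    for slot in ("{r}", "{s}"):
        if slot in out:
            counter[0] += 1
            idx = counter[0]
            token = str(idx) if idx <= 9 else f"%{idx}"
            out = out.replace(slot, token)
    return out


def _assemble_smiles(
    scaffold: str, motif_counts: Mapping[str, int], substituents: list[str], rng: np.random.Generator
) -> str:
    counter = [0]
    fragments = [scaffold]
    for motif in MOTIF_FRAGMENTS:  # fixed vocabulary order
        fragments.extend([MOTIF_FRAGMENTS[motif]] * motif_counts.get(motif, 0))
    fragments.extend(substituents)
    tail = fragments[1:]
    rng.shuffle(tail)
    smiles = "".join("C(" + _fill_rings(frag, counter) + ")" for frag in [fragments[0]] + tail)
    canonical = Chem.CanonSmiles(smiles)
    if not canonical:
        raise PipelineError(f"grammar produced an unparseable SMILES: {smiles}")
    return canonical


def generate_library(config: SyntheticConfig) -> SyntheticLibrary:
    """Generate a seeded synthetic library with planted motif-activity signal."""
    rng = np.random.default_rng(config.seed)
    records: list[ChemicalRecord] = []
    truth: dict[str, dict] = {}
    vocab = list(MOTIF_FRAGMENTS)
    for i in range(config.n_chemicals):
        scaffold = _SCAFFOLDS[rng.integers(len(_SCAFFOLDS))]
        motif_counts: dict[str, int] = {}
        for motif in vocab:
            if rng.random() < config.motif_prevalence:
                extra = int(rng.binomial(config.motif_extra_copies, 0.5)) if config.motif_extra_copies else 0
                motif_counts[motif] = 1 + extra
        n_subs = int(rng.integers(0, 3))
        subs = [_SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))] for _ in range(n_subs)]
        smiles = _assemble_smiles(scaffold, motif_counts, subs, rng)

        p_active = activity_probability(motif_counts, config)
        active_true = bool(rng.random() < p_active)
        label = active_true
        if config.label_noise > 0 and rng.random() < config.label_noise:
            label = not label

        cid = f"SYN{i:05d}"
        records.append(
            ChemicalRecord(
                id=cid,
                smiles_raw=smiles,
                casrn=f"9999-{i:05d}-0",
                name=f"synthetic-{i}",
                labels={config.endpoint: "active" if label else "inactive"},
            )
        )
        truth[cid] = {
            "motifs": motif_counts,
            "active_true": active_true,
            "label": "active" if label else "inactive",
        }
    return SyntheticLibrary(records=records, truth=truth, config=config)


def write_synthetic_library(library: SyntheticLibrary, out_dir: str | Path) -> None:
    """Write library.csv, labels.csv and truth.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_library_csv(library.records, out / "library.csv")
    write_labels_csv(library.records, out / "labels.csv")
    with open(out / "truth.json", "w") as handle:
        json.dump(library.truth, handle, indent=1, sort_keys=True)
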