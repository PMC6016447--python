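"""Synthetic labelled datasets with a planted structure-label rule.

Real gelation outcomes for this compound family are experimental and cannot
be shipped; every demo and test dataset here is SYNTHETIC.  Labels come from
a planted rule on computable descriptors — by default a hydrophobicity
threshold (AlogP above the library median), reflecting that gelation
propensity in functionalised dipeptides tracks the hydrophobic/aromatic
character of the molecule — optionally corrupted by independent Bernoulli
label noise.  The enumeration mechanism, class structure (a 34-compound
17/17 training set, a 21-compound 4/17 test set) and modelling workflow are
faithful to the real study design; the labels are not experimental data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .chem import (
    GELATOR,
    NON_GELATOR,
    BuildingBlock,
    CompoundRecord,
    VirtualLibrary,
    enumerate_library,
    load_building_blocks,
)
from .descriptors import PHYSCHEM_NAMES, compute_physchem

logger = logging.getLogger(__name__)


def default_building_blocks() -> list[BuildingBlock]:
    """The packaged block file: 10 caps spanning the naphthalene /
    tetrahydronaphthalene / carbazole / fluorene / long-alkyl / substituted-
    aromatic families and the 8 amino acids (Gly, Ala, Val, Leu, Ile, Phe,
    Met, Tyr)."""
    ref = resources.files("gelscreen.data") / "building_blocks.csv"
    with resources.as_file(ref) as path:
        return load_building_blocks(path)


@dataclass(frozen=True)
class PlantedRule:
    """Linear threshold rule on named physchem descriptors.

    Label = gelator iff  sum_i weights[name_i] * descriptor_i > threshold.
    ``threshold="median"`` resolves to the median of the weighted sum over
    the dataset being labelled.
    """

    weights: dict[str, float]
    threshold: float | str = "median"

    def __post_init__(self):
        unknown = set(self.weights) - set(PHYSCHEM_NAMES)
        if unknown:
            raise ValueError(f"rule references unknown descriptors: {sorted(unknown)}")

    def scores(self, records: list[CompoundRecord]) -> np.ndarray:
        idx = {n: i for i, n in enumerate(PHYSCHEM_NAMES)}
        phys = np.array([compute_physchem(r).physchem for r in records])
        s = np.zeros(len(records))
        for name, w in self.weights.items():
            s += w * phys[:, idx[name]]
        return s

    def labels(self, records: list[CompoundRecord]) -> np.ndarray:
        s = self.scores(records)
        thr = float(np.median(s)) if self.threshold == "median" else float(self.threshold)
        # scores within float noise of the threshold count as not exceeding it,
        # so near-duplicate descriptor values cannot straddle the boundary
        return (s > thr + 1e-9).astype(int)


DEFAULT_RULE = PlantedRule(weights={"alogp": 1.0}, threshold="median")


def generate_fixture_dataset(
    n_caps: int,
    n_aas: int,
    rule: PlantedRule = DEFAULT_RULE,
    noise: float = 0.0,
    seed: int = 0,
    include_monopeptides: bool = True,
    blocks: list[BuildingBlock] | None = None,
) -> list[CompoundRecord]:
    """Enumerate a library from the first blocks and plant noisy rule labels.

    The observed label is rule(descriptors) XOR Bernoulli(noise).
    Deterministic for a fixed seed.
    """
    if not 0 <= noise < 0.5:
        raise ValueError("noise must be in [0, 0.5)")
    blocks = blocks if blocks is not None else default_building_blocks()
    caps = [b for b in blocks if b.kind == "cap"][:n_caps]
    aas = [b for b in blocks if b.kind == "amino_acid"][:n_aas]
    if len(caps) < n_caps or len(aas) < n_aas:
        raise ValueError("not enough building blocks of the requested kinds")
    library = enumerate_library(caps, aas, include_monopeptides=include_monopeptides)
    true = rule.labels(library.compounds)
    rng = np.random.default_rng(seed)
    flips = rng.random(len(true)) < noise
    observed = true ^ flips
    records = [
        replace(rec, label=GELATOR if lab else NON_GELATOR, source="synthetic")
        for rec, lab in zip(library.compounds, observed)
    ]
    logger.info(
        "fixture dataset: n=%d, gelators=%d, non-gelators=%d, flipped=%d",
        len(records), int(observed.sum()), int((1 - observed).sum()), int(flips.sum()),
    )
    return records


@dataclass
class FixtureSuite:
    """Deterministic demo data mirroring the study's class structure."""

    blocks: list[BuildingBlock]
    train: list[CompoundRecord]  # 34 compounds, 17 gelators / 17 non-gelators
    test: list[CompoundRecord]   # 21 compounds, 4 gelators / 17 non-gelators
    rule: PlantedRule
    noise: float
    seed: int


def _sample_split(
    records: list[CompoundRecord],
    rng: np.random.Generator,
    wanted: list[tuple[str, int, int]],  # (source tag, n_gelators, n_non)
) -> list[list[CompoundRecord]]:
    pools = {
        GELATOR: [r for r in records if r.label == GELATOR],
        NON_GELATOR: [r for r in records if r.label == NON_GELATOR],
    }
    for pool in pools.values():
        rng.shuffle(pool)
    out = []
    for source, n_gel, n_non in wanted:
        if len(pools[GELATOR]) < n_gel or len(pools[NON_GELATOR]) < n_non:
            raise ValueError("library too small for the requested class structure")
        chunk = [replace(r, source=source) for r in pools[GELATOR][:n_gel]]
        chunk += [replace(r, source=source) for r in pools[NON_GELATOR][:n_non]]
        pools[GELATOR] = pools[GELATOR][n_gel:]
        pools[NON_GELATOR] = pools[NON_GELATOR][n_non:]
        out.append(chunk)
    return out


def build_demo(seed: int = 0, noise: float = 0.1) -> FixtureSuite:
    """Build the demo fixture suite: balanced 17/17 training set and
    imbalanced 4/17 test set drawn without overlap from the default library,
    labelled by the default hydrophobicity rule with 10% label noise."""
    blocks = default_building_blocks()
    records = generate_fixture_dataset(
        n_caps=10, n_aas=8, rule=DEFAULT_RULE, noise=noise, seed=seed, blocks=blocks
    )
    rng = np.random.default_rng(seed + 1)
    train, test = _sample_split(
        records, rng, [("training", 17, 17), ("test", 4, 17)]
    )
    return FixtureSuite(
        blocks=blocks, train=train, test=test, rule=DEFAULT_RULE, noise=noise, seed=seed
    )
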