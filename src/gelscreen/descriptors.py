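"""Molecular featurization and the MODI modelability index.

Every model consumes the same feature block: 12 physicochemical descriptors
(2D-computable, no conformers) concatenated with a folded binary circular
fingerprint (ECFP-like, radius 2, 1024 bits by default).  Physchem columns
are z-scored with center/scale parameters fitted on training rows only;
fingerprint bits are left 0/1.

The 12 descriptors cover the six structure-property drivers known to matter
for this gelator family (ring count, predicted aqueous solubility, polar
surface area, solvent-accessible surface area, AlogP, rotatable bonds) plus
six standard 0D/1D counts.  Predicted aqueous solubility is the ESOL
(Delaney) regression; the surface-area descriptor is Labute's approximate
ASA, both computable from the 2D graph.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors

from .chem import GELATOR, CompoundRecord

PHYSCHEM_NAMES: tuple[str, ...] = (
    "alogp",
    "esol_log_solubility",
    "tpsa",
    "labute_asa",
    "ring_count",
    "aromatic_ring_count",
    "rotatable_bonds",
    "mol_weight",
    "hbd_count",
    "hba_count",
    "heavy_atom_count",
    "formal_charge",
)

N_PHYSCHEM = len(PHYSCHEM_NAMES)


@dataclass(frozen=True)
class DescriptorVector:
    compound_id: str
    physchem: np.ndarray  # length 12, order PHYSCHEM_NAMES
    names: tuple[str, ...] = PHYSCHEM_NAMES

    def __post_init__(self):
        if len(self.physchem) != len(self.names):
            raise ValueError("descriptor vector length mismatch")
        if not np.all(np.isfinite(self.physchem)):
            raise ValueError(f"non-finite descriptor for {self.compound_id}")


@dataclass(frozen=True)
class FingerprintVector:
    compound_id: str
    bits: frozenset[int]
    n_bits: int

    def __post_init__(self):
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.n_bits):
            raise ValueError("fingerprint bit index out of range")


def _esol_log_solubility(mol: Chem.Mol) -> float:
    """ESOL estimated log10 aqueous solubility (mol/L), Delaney's regression."""
    clogp = Crippen.MolLogP(mol)
    mw = Descriptors.MolWt(mol)
    rb = rdMolDescriptors.CalcNumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    aromatic = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    ap = aromatic / heavy if heavy else 0.0
    return 0.16 - 0.63 * clogp - 0.0062 * mw + 0.066 * rb - 0.74 * ap


def compute_physchem(record: CompoundRecord) -> DescriptorVector:
    """Compute the 12-descriptor physicochemical block for one compound.

    Pure function of the canonical SMILES.  Raises ``ValueError`` if the
    descriptor backend fails (exotic atoms); callers exclude such compounds
    with a warning.
    """
    mol = record.mol
    if mol is None:
        raise ValueError(f"{record.id}: invalid molecule")
    try:
        values = np.array(
            [
                Crippen.MolLogP(mol),
                _esol_log_solubility(mol),
                rdMolDescriptors.CalcTPSA(mol),
                rdMolDescriptors.CalcLabuteASA(mol),
                rdMolDescriptors.CalcNumRings(mol),
                rdMolDescriptors.CalcNumAromaticRings(mol),
                rdMolDescriptors.CalcNumRotatableBonds(mol),
                Descriptors.MolWt(mol),
                rdMolDescriptors.CalcNumHBD(mol),
                rdMolDescriptors.CalcNumHBA(mol),
                mol.GetNumHeavyAtoms(),
                Chem.GetFormalCharge(mol),
            ],
            dtype=float,
        )
    except Exception as exc:  # descriptor backend failure on exotic structures
        raise ValueError(f"{record.id}: descriptor computation failed ({exc})") from exc
    return DescriptorVector(compound_id=record.id, physchem=values)


def compute_fingerprint(
    record: CompoundRecord, radius: int = 2, n_bits: int = 1024
) -> FingerprintVector:
    """Folded binary circular fingerprint (deterministic for fixed inputs)."""
    if n_bits <= 0 or (n_bits & (n_bits - 1)) != 0:
        raise ValueError(f"n_bits must be a power of two, got {n_bits}")
    mol = record.mol
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return FingerprintVector(
        compound_id=record.id, bits=frozenset(fp.GetOnBits()), n_bits=n_bits
    )


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprint lengths differ")
    union = len(a.bits | b.bits)
    return len(a.bits & b.bits) / union if union else 0.0


@dataclass
class FeatureMatrix:
    """Scaled physchem block + binary fingerprint block for a compound set."""

    compound_ids: list[str]
    X: np.ndarray  # (n, 12 + n_bits)
    names: list[str]
    center: np.ndarray  # per-column; identity (0, 1) for fingerprint columns
    scale: np.ndarray
    n_bits: int
    radius: int

    @property
    def n_physchem(self) -> int:
        return len(self.names) - self.n_bits

    @property
    def physchem(self) -> np.ndarray:
        return self.X[:, : self.n_physchem]

    @property
    def fingerprints(self) -> np.ndarray:
        return self.X[:, self.n_physchem :]


class Featurizer:
    """Computes features and freezes physchem scaling on the training set.

    ``fit`` learns per-column mean and standard deviation of the physchem
    block from the supplied (training) records; ``transform`` applies the
    frozen parameters and never updates them, so test rows cannot leak into
    the scaling.
    """

    def __init__(self, radius: int = 2, n_bits: int = 1024):
        self.radius = radius
        self.n_bits = n_bits
        self.center_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def _raw(self, records: list[CompoundRecord]) -> tuple[list[str], np.ndarray, np.ndarray]:
        ids, phys, fps = [], [], []
        for rec in records:
            try:
                d = compute_physchem(rec)
            except ValueError as exc:
                warnings.warn(f"excluding {rec.id}: {exc}", stacklevel=2)
                continue
            f = compute_fingerprint(rec, radius=self.radius, n_bits=self.n_bits)
            ids.append(rec.id)
            phys.append(d.physchem)
            row = np.zeros(self.n_bits)
            row[sorted(f.bits)] = 1.0
            fps.append(row)
        if not ids:
            raise ValueError("no featurizable compounds")
        return ids, np.asarray(phys), np.asarray(fps)

    def fit(self, records: list[CompoundRecord]) -> "Featurizer":
        _, phys, _ = self._raw(records)
        self.center_ = phys.mean(axis=0)
        sd = phys.std(axis=0, ddof=1)
        self.scale_ = np.where(sd > 0, sd, 1.0)  # constant columns pass through
        return self

    def transform(self, records: list[CompoundRecord]) -> FeatureMatrix:
        if self.center_ is None:
            raise RuntimeError("Featurizer not fitted")
        ids, phys, fps = self._raw(records)
        scaled = (phys - self.center_) / self.scale_
        X = np.hstack([scaled, fps])
        names = list(PHYSCHEM_NAMES) + [f"fp{i}" for i in range(self.n_bits)]
        center = np.concatenate([self.center_, np.zeros(self.n_bits)])
        scale = np.concatenate([self.scale_, np.ones(self.n_bits)])
        return FeatureMatrix(
            compound_ids=ids, X=X, names=names, center=center, scale=scale,
            n_bits=self.n_bits, radius=self.radius,
        )

    def fit_transform(self, records: list[CompoundRecord]) -> FeatureMatrix:
        return self.fit(records).transform(records)

    @property
    def schema(self) -> dict:
        """Feature-schema signature used to refuse mismatched model/query pairs."""
        return {
            "physchem_names": list(PHYSCHEM_NAMES),
            "radius": self.radius,
            "n_bits": self.n_bits,
        }


def modi(X_physchem_scaled: np.ndarray, labels: np.ndarray) -> float:
    """Modelability index of a binary-labelled descriptor matrix.

    MODI is the mean, over the two classes, of the fraction of compounds
    whose single nearest neighbour (Euclidean distance in the z-scored
    physchem space, self excluded, ties broken by lowest row index) carries
    the same label.  A value above 0.65 suggests the set is amenable to
    classification modelling.
    """
    X = np.asarray(X_physchem_scaled, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and labels length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"MODI needs exactly 2 classes, got {len(classes)}")
    if counts.min() < 2:
        raise ValueError("each class needs >=2 members (nearest same-class neighbour undefined)")
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
    same = y[nn] == y
    return float(np.mean([same[y == c].mean() for c in classes]))


def feature_matrix_to_csv(fm: FeatureMatrix, csv_path, sidecar_path=None) -> None:
    """Write features as CSV plus a JSON sidecar with schema and scaling."""
    df = pd.DataFrame(fm.X, columns=fm.names)
    df.insert(0, "compound_id", fm.compound_ids)
    df.to_csv(csv_path, index=False)
    sidecar = sidecar_path or str(csv_path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "physchem_names": fm.names[: fm.n_physchem],
                "radius": fm.radius,
                "n_bits": fm.n_bits,
                "center": fm.center[: fm.n_physchem].tolist(),
                "scale": fm.scale[: fm.n_physchem].tolist(),
            },
            fh,
            indent=1,
        )


def feature_matrix_from_csv(csv_path, sidecar_path=None) -> FeatureMatrix:
    df = pd.read_csv(csv_path)
    sidecar = sidecar_path or str(csv_path) + ".json"
    with open(sidecar) as fh:
        meta = json.load(fh)
    names = list(df.columns[1:])
    n_phys = len(meta["physchem_names"])
    center = np.concatenate([np.array(meta["center"]), np.zeros(meta["n_bits"])])
    scale = np.concatenate([np.array(meta["scale"]), np.ones(meta["n_bits"])])
    return FeatureMatrix(
        compound_ids=df.iloc[:, 0].astype(str).tolist(),
        X=df.iloc[:, 1:].to_numpy(float),
        names=names,
        center=center,
        scale=scale,
        n_bits=meta["n_bits"],
        radius=meta["radius"],
    )


def labels_to_binary(records: list[CompoundRecord]) -> np.ndarray:
    """1 = gelator (positive class), 0 = non-gelator; unknown labels rejected."""
    y = []
    for rec in records:
        if rec.label == "unknown":
            raise ValueError(f"{rec.id}: unlabelled compound in a labelled set")
        y.append(1 if rec.label == GELATOR else 0)
    return np.asarray(y, dtype=int)
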