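"""Compounds, building blocks and combinatorial library enumeration.

The gelator family modelled here is the N-functionalised amino acid /
dipeptide class: an aromatic or long-alkyl "cap" amide-bonded to one or two
amino-acid residues with a free C-terminal carboxylic acid.  Building blocks
are SMILES fragments carrying dummy-atom attachment points written with atom
map numbers (``[*:1]``): a cap has exactly one attachment point (its acyl
carbon), an amino-acid residue has two (N-terminus ``[*:1]``, C-terminus
``[*:2]``).  Products are assembled by fusing matching attachment points,
which yields the cap-N amide and the AA-AA peptide bond.
"""

from __future__ import annotations

import csv
import hashlib
import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")

GELATOR = "gelator"
NON_GELATOR = "non-gelator"
UNKNOWN = "unknown"
LABELS = frozenset({GELATOR, NON_GELATOR, UNKNOWN})

SOURCES = frozenset({"training", "test", "validation", "virtual", "synthetic"})

#: accepted spellings for the binary gelation outcome in input tables
_LABEL_TOKENS = {
    "yes": GELATOR,
    "y": GELATOR,
    "1": GELATOR,
    "gelator": GELATOR,
    "no": NON_GELATOR,
    "n": NON_GELATOR,
    "0": NON_GELATOR,
    "non-gelator": NON_GELATOR,
    "nongelator": NON_GELATOR,
    "non_gelator": NON_GELATOR,
    "": UNKNOWN,
    "unknown": UNKNOWN,
    "na": UNKNOWN,
}


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


def canonical_smiles(smiles: str) -> str:
    """Return the canonical SMILES, raising :class:`InvalidSmilesError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def parse_label(token: str) -> str:
    key = str(token).strip().lower()
    if key not in _LABEL_TOKENS:
        raise ValueError(f"unknown label token: {token!r}")
    return _LABEL_TOKENS[key]


@dataclass(frozen=True)
class CompoundRecord:
    """A molecule with an optional binary gelation label.

    ``smiles`` is stored in canonical form so equality of records implies
    identity of structures.
    """

    id: str
    smiles: str
    label: str = UNKNOWN
    source: str = "training"

    def __post_init__(self):
        object.__setattr__(self, "smiles", canonical_smiles(self.smiles))
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {sorted(LABELS)}, got {self.label!r}")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {sorted(SOURCES)}, got {self.source!r}")

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


def _attachment_points(mol: Chem.Mol) -> list[int]:
    return sorted(
        a.GetAtomMapNum()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 0 and a.GetAtomMapNum() > 0
    )


@dataclass(frozen=True)
class BuildingBlock:
    """A cap or amino-acid fragment with dummy-atom attachment points.

    Caps carry one attachment point ``[*:1]`` on the acyl carbon; amino acids
    carry ``[*:1]`` on the backbone nitrogen and ``[*:2]`` on the carbonyl
    carbon.
    """

    id: str
    kind: str  # "cap" | "amino_acid"
    fragment_smiles: str
    name: str = ""

    def __post_init__(self):
        if self.kind not in ("cap", "amino_acid"):
            raise ValueError(f"kind must be 'cap' or 'amino_acid', got {self.kind!r}")
        mol = Chem.MolFromSmiles(self.fragment_smiles)
        if mol is None:
            raise InvalidSmilesError(f"unparseable fragment SMILES: {self.fragment_smiles!r}")
        points = _attachment_points(mol)
        expected = [1] if self.kind == "cap" else [1, 2]
        if points != expected:
            raise ValueError(
                f"block {self.id!r} ({self.kind}) must have attachment points "
                f"{expected}, found {points}"
            )

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.fragment_smiles)


@dataclass
class VirtualLibrary:
    """Enumerated cap-AA(-AA) products with building-block provenance.

    ``provenance`` maps compound id to all (cap_id, aa1_id, aa2_id-or-None)
    routes producing that structure; duplicates arising from distinct routes
    are merged after canonicalization.  ``n_enumerated`` is the pre-merge
    product count governed by the combinatorial formula
    ``n_caps * (n_aa + n_aa**2)`` (or ``n_caps * n_aa**2`` dipeptides-only).
    """

    compounds: list[CompoundRecord]
    provenance: dict[str, list[tuple[str, str, str | None]]]
    config_hash: str
    n_enumerated: int

    def __len__(self) -> int:
        return len(self.compounds)


def load_compounds(path, fmt: str | None = None, source: str = "training") -> list[CompoundRecord]:
    """Load compounds from a CSV (columns: id, smiles, label) or .smi file.

    Rows with unparseable SMILES are rejected; their 1-based row numbers are
    reported through a warning.  A row with an unrecognised label token, or a
    file yielding zero valid rows, raises ``ValueError``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "smi" if path.suffix.lower() in (".smi", ".smiles") else "csv"
    rows: list[tuple[int, str, str, str]] = []  # (row_no, id, smiles, label_token)
    if fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "smiles" not in [f.lower() for f in reader.fieldnames]:
                raise ValueError(f"{path}: CSV must have a 'smiles' column")
            fields = {f.lower(): f for f in reader.fieldnames}
            for i, row in enumerate(reader, start=2):  # header is row 1
                smiles = (row.get(fields["smiles"]) or "").strip()
                cid = (row.get(fields.get("id", ""), "") or f"cpd{i - 1}").strip() or f"cpd{i - 1}"
                label = (row.get(fields.get("label", ""), "") or "").strip()
                rows.append((i, cid, smiles, label))
    elif fmt == "smi":
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                rows.append((i, parts[1] if len(parts) > 1 else f"cpd{i}", parts[0], ""))
    else:
        raise ValueError(f"unknown format {fmt!r}")

    records, rejected = [], []
    for row_no, cid, smiles, token in rows:
        label = parse_label(token)  # unknown token -> hard error, by contract
        try:
            records.append(CompoundRecord(id=cid, smiles=smiles, label=label, source=source))
        except InvalidSmilesError:
            rejected.append(row_no)
    if rejected:
        warnings.warn(
            f"{path}: rejected {len(rejected)} row(s) with invalid SMILES: {rejected}",
            stacklevel=2,
        )
    if not records:
        raise ValueError(f"{path}: no valid compound rows")
    return records


def load_building_blocks(path) -> list[BuildingBlock]:
    """Load building blocks from a CSV with columns id, kind, fragment_smiles, name."""
    blocks = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            blocks.append(
                BuildingBlock(
                    id=row["id"].strip(),
                    kind=row["kind"].strip(),
                    fragment_smiles=row["fragment_smiles"].strip(),
                    name=(row.get("name") or "").strip(),
                )
            )
    if not blocks:
        raise ValueError(f"{path}: no building blocks")
    return blocks


def _relabel_map_nums(mol: Chem.Mol, mapping: dict[int, int]) -> Chem.Mol:
    out = Chem.RWMol(mol)
    for atom in out.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() in mapping:
            atom.SetAtomMapNum(mapping[atom.GetAtomMapNum()])
    return out.GetMol()


_HYDROXYL = Chem.MolFromSmiles("[*:1]O")


def assemble(cap: BuildingBlock, residues: list[BuildingBlock]) -> str:
    """Join a cap to a sequence of amino-acid residues by amide bonds.

    The cap's acyl attachment bonds to the first residue's nitrogen, each
    residue's carbonyl to the next residue's nitrogen, and the final carbonyl
    is closed with a hydroxyl giving the free C-terminal acid.  Returns the
    canonical product SMILES.
    """
    if cap.kind != "cap":
        raise ValueError(f"{cap.id!r} is not a cap")
    if not residues or any(r.kind != "amino_acid" for r in residues):
        raise ValueError("residues must be one or more amino_acid blocks")
    pieces = [cap.mol]
    for i, res in enumerate(residues, start=1):
        pieces.append(_relabel_map_nums(res.mol, {1: i, 2: i + 1}))
    pieces.append(_relabel_map_nums(_HYDROXYL, {1: len(residues) + 1}))
    combo = pieces[0]
    for p in pieces[1:]:
        combo = Chem.CombineMols(combo, p)
    product = Chem.molzip(combo)
    if product is None:  # pragma: no cover - molzip raises rather than returning None
        raise ValueError(f"could not join {cap.id} + {[r.id for r in residues]}")
    Chem.SanitizeMol(product)
    return Chem.MolToSmiles(product)


def enumerate_library(
    caps: list[BuildingBlock],
    aas: list[BuildingBlock],
    include_monopeptides: bool = True,
) -> VirtualLibrary:
    """Enumerate all cap-AA and (optionally) cap-AA-AA products.

    Pre-merge product count is ``n_caps * (n_aa + n_aa**2)`` with
    monopeptides, ``n_caps * n_aa**2`` without.  Structures identical after
    canonicalization are merged; every producing route is kept in the
    provenance map.
    """
    if not caps or not aas:
        raise ValueError("need at least one cap and one amino acid")
    routes: list[tuple[str, tuple[str, str, str | None]]] = []
    if include_monopeptides:
        for cap, aa in itertools.product(caps, aas):
            routes.append((assemble(cap, [aa]), (cap.id, aa.id, None)))
    for cap, aa1, aa2 in itertools.product(caps, aas, aas):
        routes.append((assemble(cap, [aa1, aa2]), (cap.id, aa1.id, aa2.id)))

    by_smiles: dict[str, list[tuple[str, str, str | None]]] = {}
    for smi, route in routes:
        by_smiles.setdefault(smi, []).append(route)

    digest = hashlib.sha256(
        repr(
            (
                sorted((c.id, c.fragment_smiles) for c in caps),
                sorted((a.id, a.fragment_smiles) for a in aas),
                include_monopeptides,
            )
        ).encode()
    ).hexdigest()[:16]

    compounds, provenance = [], {}
    for idx, (smi, route_list) in enumerate(sorted(by_smiles.items()), start=1):
        cid = f"vl{idx:04d}"
        compounds.append(CompoundRecord(id=cid, smiles=smi, label=UNKNOWN, source="virtual"))
        provenance[cid] = route_list
    logger.info(
        "enumerated %d products (%d unique) from %d caps x %d amino acids",
        len(routes), len(compounds), len(caps), len(aas),
    )
    return VirtualLibrary(
        compounds=compounds,
        provenance=provenance,
        config_hash=digest,
        n_enumerated=len(routes),
    )


def write_smi(records: list[CompoundRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.id}\n")


def write_csv(records: list[CompoundRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "label"])
        label_out = {GELATOR: "yes", NON_GELATOR: "no", UNKNOWN: ""}
        for rec in records:
            writer.writerow([rec.id, rec.smiles, label_out[rec.label]])
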