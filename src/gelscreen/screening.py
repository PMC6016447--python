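"""Virtual screening: enumerate -> featurize -> AD-filter -> consensus -> rank.

Out-of-domain compounds are annotated but not predicted: the applicability
domain acts as a trust warning, and consensus calls are reported only for
in-domain structures.  Candidates are the top-m predicted gelators and
top-m predicted non-gelators by consensus likelihood.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem import CompoundRecord, VirtualLibrary
from .descriptors import Featurizer
from .domain import ApplicabilityDomain
from .modeling import TrainedModel, consensus_predict, predict_proba


@dataclass
class ScreenRow:
    id: str
    smiles: str
    in_domain: bool
    reasons: list[str]
    per_model_p: dict[str, float] | None
    call: str | None  # "yes" | "no" | None when out of domain
    likelihood: float | None  # percent


@dataclass
class ScreenReport:
    n_enumerated: int
    n_in_domain: int
    rows: list[ScreenRow]
    selected_candidates: list[ScreenRow]

    def to_json(self) -> str:
        def row(r: ScreenRow) -> dict:
            return {
                "id": r.id, "smiles": r.smiles, "in_domain": r.in_domain,
                "reasons": r.reasons, "per_model_p": r.per_model_p,
                "call": r.call, "likelihood": r.likelihood,
            }
        return json.dumps(
            {
                "n_enumerated": self.n_enumerated,
                "n_in_domain": self.n_in_domain,
                "rows": [row(r) for r in self.rows],
                "selected_candidates": [row(r) for r in self.selected_candidates],
            },
            indent=1,
        )

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "smiles", "in_domain", "call", "likelihood_pct", "reasons"])
            for r in self.rows:
                w.writerow([
                    r.id, r.smiles, int(r.in_domain), r.call or "",
                    f"{r.likelihood:.1f}" if r.likelihood is not None else "",
                    "; ".join(r.reasons),
                ])


def screen(
    library: VirtualLibrary,
    models: list[TrainedModel],
    ad: ApplicabilityDomain,
    featurizer: Featurizer,
    m_gelators: int = 4,
    m_non_gelators: int = 5,
) -> ScreenReport:
    """Screen an enumerated library with a model consensus inside the AD.

    Models failing their quality gates trigger a warning but are not
    excluded — gate verdicts are the user's call.  Rows are sorted in-domain
    first, predicted gelators before non-gelators, by descending likelihood
    within each call class.
    """
    for m in models:
        if m.evaluation is not None and m.evaluation.verdict != "good":
            warnings.warn(
                f"model {m.family} did not pass its quality gate "
                f"({m.evaluation.failed_criteria})",
                stacklevel=2,
            )
    flags = {rec.id: ad.in_domain(rec) for rec in library.compounds}
    in_dom = [rec for rec in library.compounds if flags[rec.id][0]]
    rows: list[ScreenRow] = []
    if in_dom:
        fm = featurizer.transform(in_dom)
        calls, likelihood, _ = consensus_predict(models, fm)
        per_model = {m.family: predict_proba(m, fm) for m in models}
        for i, rec in enumerate(in_dom):
            rows.append(
                ScreenRow(
                    id=rec.id,
                    smiles=rec.smiles,
                    in_domain=True,
                    reasons=[],
                    per_model_p={f: float(p[i]) for f, p in per_model.items()},
                    call="yes" if calls[i] else "no",
                    likelihood=float(likelihood[i]),
                )
            )
    for rec in library.compounds:
        ok, reasons = flags[rec.id]
        if not ok:
            rows.append(
                ScreenRow(
                    id=rec.id, smiles=rec.smiles, in_domain=False,
                    reasons=reasons, per_model_p=None, call=None, likelihood=None,
                )
            )
    rows.sort(
        key=lambda r: (
            not r.in_domain,
            {"yes": 0, "no": 1, None: 2}[r.call],
            -(r.likelihood or 0.0),
            r.id,
        )
    )
    gel = [r for r in rows if r.call == "yes"][:m_gelators]
    non = [r for r in rows if r.call == "no"][:m_non_gelators]
    return ScreenReport(
        n_enumerated=len(library.compounds),
        n_in_domain=len(in_dom),
        rows=rows,
        selected_candidates=gel + non,
    )
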