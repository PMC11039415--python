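"""Result surfaces: cross-tabulation, headline proportions, yields,
and algorithm-vs-adjudication agreement.

The central artefact is the 7x3 cross-tabulation of FEV1 impairment band
(rows: normal .. very severe, plus missing) against FEV1:FVC ratio status
(columns: >= 0.7, < 0.7, missing), with marginals.  Headline percentages
are rounded half-away-from-zero to one decimal so printed values are
stable and reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import Obstruction, Severity, SpirometryClassification

__all__ = [
    "SEVERITY_ROWS",
    "RATIO_COLS",
    "CrossTab",
    "build_crosstab",
    "headline_proportions",
    "facility_yield",
    "AgreementReport",
    "validate_against_truth",
    "round_half_up",
]

logger = logging.getLogger(__name__)

SEVERITY_ROWS = [s.value for s in (
    Severity.NORMAL, Severity.MILD, Severity.MODERATE,
    Severity.MODERATELY_SEVERE, Severity.SEVERE, Severity.VERY_SEVERE,
    Severity.MISSING,
)]

#: ratio columns; a classification's obstruction status picks the column
RATIO_COLS = ["ratio_ge_0.7", "ratio_lt_0.7", "ratio_missing"]

_OBSTRUCTION_TO_COL = {
    Obstruction.NOT_OBSTRUCTED: "ratio_ge_0.7",
    Obstruction.OBSTRUCTED: "ratio_lt_0.7",
    Obstruction.MISSING: "ratio_missing",
}


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention printed reports use)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CrossTab:
    """Severity-by-ratio contingency table with marginals."""

    cells: pd.DataFrame  # index SEVERITY_ROWS, columns RATIO_COLS, int counts

    def __post_init__(self):
        if list(self.cells.index) != SEVERITY_ROWS or list(self.cells.columns) != RATIO_COLS:
            raise ValueError("cells must be indexed by severity rows x ratio columns")
        if (self.cells.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def row_totals(self) -> pd.Series:
        return self.cells.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.cells.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.cells.values.sum())

    def to_frame(self) -> pd.DataFrame:
        """Table with the Total row and column attached."""
        frame = self.cells.copy()
        frame["total"] = self.row_totals
        total_row = frame.sum(axis=0)
        frame.loc["total"] = total_row
        return frame

    def render_text(self) -> str:
        """Plain-text rendering of the table with marginals."""
        frame = self.to_frame()
        header = ["FEV1 % predicted"] + list(frame.columns)
        widths = [max(len(header[0]), max(len(i) for i in frame.index))] + [
            max(len(c), 8) for c in frame.columns
        ]
        lines = ["  ".join(h.rjust(w) for h, w in zip(header, widths))]
        for idx, row in frame.iterrows():
            cells = [str(idx).rjust(widths[0])] + [
                str(int(v)).rjust(w) for v, w in zip(row, widths[1:])
            ]
            lines.append("  ".join(cells))
        return "\n".join(lines)


def build_crosstab(
    classifications: Sequence[SpirometryClassification],
) -> CrossTab:
    """Tally each record into exactly one (severity, ratio-status) cell."""
    cells = pd.DataFrame(
        0, index=SEVERITY_ROWS, columns=RATIO_COLS, dtype=int
    )
    for rec in classifications:
        cells.loc[rec.severity.value, _OBSTRUCTION_TO_COL[rec.obstruction]] += 1
    return CrossTab(cells=cells)


def headline_proportions(crosstab: CrossTab) -> tuple[float, float]:
    """(percent obstructed, percent severe-or-worse), one decimal.

    Obstructed = the < 0.7 ratio column over all studies; severe-or-worse
    = the severe plus very-severe rows over all studies.  Both are on the
    percent scale.
    """
    n = crosstab.grand_total
    if n == 0:
        raise ValueError("undefined proportions: cross-tab is empty")
    pct_obstructed = round_half_up(100.0 * crosstab.col_totals["ratio_lt_0.7"] / n)
    severe_rows = (
        crosstab.row_totals[Severity.SEVERE.value]
        + crosstab.row_totals[Severity.VERY_SEVERE.value]
    )
    pct_severe = round_half_up(100.0 * severe_rows / n)
    return pct_obstructed, pct_severe


def facility_yield(
    classifications: Sequence[SpirometryClassification],
    procedures: Sequence,
) -> pd.DataFrame:
    """Per-facility extraction yield for the ratio and FEV1 values.

    Yield = studies with an extracted quantitative value / PFTs performed
    at the facility, as fractions.
    """
    facility_of = {p.study_id: p.facility_id for p in procedures}
    n_pft: dict[str, int] = {}
    for p in procedures:
        n_pft[p.facility_id] = n_pft.get(p.facility_id, 0) + 1

    n_ratio: dict[str, int] = {}
    n_fev1: dict[str, int] = {}
    for rec in classifications:
        fid = facility_of.get(rec.study_id)
        if fid is None:
            continue
        if rec.ratio_value is not None:
            n_ratio[fid] = n_ratio.get(fid, 0) + 1
        if rec.fev1_pct_pred is not None:
            n_fev1[fid] = n_fev1.get(fid, 0) + 1

    rows = []
    for fid in sorted(n_pft):
        total = n_pft[fid]
        rows.append(
            {
                "facility_id": fid,
                "n_pft": total,
                "n_ratio_extracted": n_ratio.get(fid, 0),
                "n_fev1_extracted": n_fev1.get(fid, 0),
                "ratio_yield": n_ratio.get(fid, 0) / total if total else 0.0,
                "fev1_yield": n_fev1.get(fid, 0) / total if total else 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "facility_id", "n_pft", "n_ratio_extracted", "n_fev1_extracted",
            "ratio_yield", "fev1_yield",
        ],
    ).set_index("facility_id")


@dataclass(frozen=True)
class AgreementReport:
    """Algorithm-vs-reference agreement on a seeded random sample."""

    n: int
    obstruction_matches: int
    severity_matches: int
    obstruction_confusion: pd.DataFrame
    severity_confusion: pd.DataFrame
    discordant_obstruction: list[str] = dc_field(default_factory=list)
    discordant_severity: list[str] = dc_field(default_factory=list)

    @property
    def obstruction_accuracy(self) -> float:
        return self.obstruction_matches / self.n if self.n else float("nan")

    @property
    def severity_accuracy(self) -> float:
        return self.severity_matches / self.n if self.n else float("nan")


def validate_against_truth(
    predicted: Sequence[SpirometryClassification],
    truth: pd.DataFrame,
    n_sample: Optional[int] = None,
    seed: int = 0,
) -> AgreementReport:
    """Compare pipeline output against reference labels on a random sample.

    ``truth`` needs columns ``study_id``, ``true_obstruction``,
    ``true_severity``.  Sampling is without replacement over the shared
    study ids (sorted first, so record order is irrelevant); missing
    predicted vs missing reference counts as a match — correctly
    determining a value is absent is itself a correct determination.
    """
    pred_by_id = {p.study_id: p for p in predicted}
    truth_by_id = {
        str(row.study_id): (str(row.true_obstruction), str(row.true_severity))
        for row in truth.itertuples(index=False)
    }
    shared = sorted(set(pred_by_id) & set(truth_by_id))
    if not shared:
        raise ValueError("predicted and truth share no study_ids")

    if n_sample is None or n_sample >= len(shared):
        if n_sample is not None and n_sample > len(shared):
            logger.warning(
                "n_sample %d exceeds population %d; using all", n_sample, len(shared)
            )
        sample = shared
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(shared), size=n_sample, replace=False)
        sample = [shared[i] for i in sorted(idx)]

    obs_labels = [o.value for o in Obstruction]
    sev_labels = SEVERITY_ROWS
    obs_conf = pd.DataFrame(0, index=obs_labels, columns=obs_labels, dtype=int)
    sev_conf = pd.DataFrame(0, index=sev_labels, columns=sev_labels, dtype=int)

    obs_match = sev_match = 0
    disc_obs: list[str] = []
    disc_sev: list[str] = []
    for sid in sample:
        pred = pred_by_id[sid]
        true_obs, true_sev = truth_by_id[sid]
        obs_conf.loc[true_obs, pred.obstruction.value] += 1
        sev_conf.loc[true_sev, pred.severity.value] += 1
        if pred.obstruction.value == true_obs:
            obs_match += 1
        else:
            disc_obs.append(sid)
        if pred.severity.value == true_sev:
            sev_match += 1
        else:
            disc_sev.append(sid)

    return AgreementReport(
        n=len(sample),
        obstruction_matches=obs_match,
        severity_matches=sev_match,
        obstruction_confusion=obs_conf,
        severity_confusion=sev_conf,
        discordant_obstruction=disc_obs,
        discordant_severity=disc_sev,
    )
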