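"""Aggregate per-cell gate labels into per-well statistics, normalize to
DMSO controls, fit time-resolved dose-response, compute growth rates and
emit per-compound flagging certificates."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class QuantifyError(ValueError):
    pass


NUCLEI_CLASSES = ("healthy", "pyknosed", "fragmented")
VIA_CLASSES = ("healthy", "early_apoptotic", "late_apoptotic", "necrotic", "lysed")
FUCCI_CLASSES = ("red", "green", "yellow")

#: flagging rules: id -> (summary column, direction, default threshold)
DEFAULT_FLAG_RULES: dict[str, tuple[str, str, float]] = {
    "hio_gt_50": ("hio_ratio", ">", 0.5),
    "healthy_nuclei_lt_50": ("frac_healthy_nuclei", "<", 0.5),
    "pyknosed_gt_50": ("frac_pyknosed_nuclei", ">", 0.5),
    "fragmented_gt_50": ("frac_fragmented_nuclei", ">", 0.5),
    "tubulin_gt_50": ("frac_tubulin_effect", ">", 0.5),
    "mito_gt_50": ("frac_mito_increased", ">", 0.5),
    "membrane_gt_50": ("frac_membrane_permeable", ">", 0.5),
}


@dataclass
class WellSummary:
    """Per-well, per-timepoint population statistics.

    ``fractions`` holds one dict per partition (nuclei / viability /
    fucci), each summing to 1 over its classes when defined; phenotype
    fractions are computed among healthy-nucleus cells only, the
    mitochondrial fraction among Annexin-evaluated cells only.
    """

    well: str
    timepoint: float
    compound: str | None = None
    concentration: float = 0.0
    cell_line: str = ""
    role: str = "treatment"
    n_objects: int = 0
    n_hio: int = 0
    n_normal: int = 0
    counts: dict = field(default_factory=dict)
    fractions: dict = field(default_factory=dict)
    hio_ratio: float | None = None
    healthy_count: int = 0
    healthy_nuclei_norm: float | None = None
    growth_rate: float | None = None
    frac_tubulin_effect: float | None = None
    frac_mito_increased: float | None = None
    frac_membrane_permeable: float | None = None
    low_count_flag: bool = False

    def to_row(self) -> dict:
        row = {
            "well": self.well,
            "timepoint": self.timepoint,
            "compound": self.compound,
            "concentration": self.concentration,
            "cell_line": self.cell_line,
            "role": self.role,
            "n_objects": self.n_objects,
            "n_hio": self.n_hio,
            "n_normal": self.n_normal,
            "hio_ratio": self.hio_ratio,
            "healthy_count": self.healthy_count,
            "healthy_nuclei_norm": self.healthy_nuclei_norm,
            "growth_rate": self.growth_rate,
            "frac_tubulin_effect": self.frac_tubulin_effect,
            "frac_mito_increased": self.frac_mito_increased,
            "frac_membrane_permeable": self.frac_membrane_permeable,
            "low_count_flag": self.low_count_flag,
        }
        for part, fracs in self.fractions.items():
            suffix = "nuclei" if part == "nuclei" else part
            for cls, v in fracs.items():
                row[f"frac_{cls}_{suffix}" if part == "nuclei" else f"frac_{part}_{cls}"] = v
        return row


def _partition_fractions(labels: pd.Series, classes: Sequence[str]) -> dict | None:
    valid = labels.dropna()
    valid = valid[valid.isin(classes)]
    if valid.empty:
        return None
    counts = valid.value_counts()
    total = int(counts.sum())
    return {c: counts.get(c, 0) / total for c in classes}


def well_fractions(
    cell_records: pd.DataFrame,
    well: str = "",
    timepoint: float = 0.0,
    min_count: int = 50,
    **meta,
) -> WellSummary:
    """Population counts and fractions for one well/timepoint.

    FUCCI fractions are computed over labeled (red/green/yellow)
    healthy-nucleus cells only; unlabeled cells are excluded from the
    denominator. Zero cells give null fractions and a low-count flag.
    """
    s = WellSummary(well=well, timepoint=timepoint, **meta)
    n = len(cell_records)
    s.n_objects = n
    if n == 0:
        s.low_count_flag = True
        return s

    hio = cell_records.get("label_hio")
    if hio is not None:
        s.n_hio = int((hio == "high_intensity_object").sum())
        s.hio_ratio = s.n_hio / n
        s.n_normal = n - s.n_hio
    else:
        s.n_normal = n
        s.hio_ratio = 0.0
    s.low_count_flag = s.n_normal < min_count

    counts: dict = {}
    fractions: dict = {}
    if "label_nuclei" in cell_records:
        lab = cell_records["label_nuclei"]
        counts["nuclei"] = {c: int((lab == c).sum()) for c in NUCLEI_CLASSES}
        fr = _partition_fractions(lab, NUCLEI_CLASSES)
        if fr is not None:
            fractions["nuclei"] = fr
        s.healthy_count = counts["nuclei"]["healthy"]
    if "label_via" in cell_records:
        lab = cell_records["label_via"]
        counts["viability"] = {c: int((lab == c).sum()) for c in VIA_CLASSES}
        fr = _partition_fractions(lab, VIA_CLASSES)
        if fr is not None:
            fractions["viability"] = fr
    if "label_fucci" in cell_records:
        lab = cell_records["label_fucci"]
        counts["fucci"] = {
            c: int((lab == c).sum()) for c in (*FUCCI_CLASSES, "unlabeled")
        }
        fr = _partition_fractions(lab, FUCCI_CLASSES)  # unlabeled excluded
        if fr is not None:
            fractions["fucci"] = fr
    s.counts = counts
    s.fractions = fractions

    healthy_mask = (
        cell_records["label_nuclei"] == "healthy"
        if "label_nuclei" in cell_records
        else pd.Series(False, index=cell_records.index)
    )
    if "label_tubulin" in cell_records and healthy_mask.any():
        lab = cell_records.loc[healthy_mask, "label_tubulin"].dropna()
        s.frac_tubulin_effect = float((lab == "effect").mean()) if len(lab) else None
    if "label_membrane" in cell_records and healthy_mask.any():
        lab = cell_records.loc[healthy_mask, "label_membrane"].dropna()
        s.frac_membrane_permeable = float((lab == "permeable").mean()) if len(lab) else None
    if "label_mito" in cell_records and healthy_mask.any():
        lab = cell_records.loc[healthy_mask, "label_mito"].dropna()
        lab = lab[lab != "not_evaluated"]
        s.frac_mito_increased = float((lab == "increased").mean()) if len(lab) else None
    return s


def summaries_to_table(summaries: Iterable[WellSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])


def normalize_to_dmso(summaries: list[WellSummary]) -> list[WellSummary]:
    """Set ``healthy_nuclei_norm`` on every summary: healthy-nuclei count
    divided by the arithmetic mean of the DMSO-control wells' healthy
    counts at the same timepoint. The mean of the DMSO wells' normalized
    values is 1 by construction."""
    by_tp: dict[float, list[WellSummary]] = {}
    for s in summaries:
        by_tp.setdefault(s.timepoint, []).append(s)
    for tp, group in by_tp.items():
        dmso = [s for s in group if s.role == "dmso_control"]
        if not dmso:
            raise QuantifyError(f"no DMSO control wells at timepoint {tp}")
        denom = float(np.mean([s.healthy_count for s in dmso]))
        if denom <= 0:
            raise QuantifyError(f"DMSO healthy count is zero at timepoint {tp}")
        for s in group:
            s.healthy_nuclei_norm = s.healthy_count / denom
    return summaries


def growth_rate(x_c: float, x_0: float, x_ctrl: float) -> float:
    """Normalized growth rate: 2^(log2(x_c/x_0) / log2(x_ctrl/x_0)) - 1.

    1 means control-like growth, 0 stasis, negative net cell loss.
    Requires a growing control (x_ctrl > x_0) and positive counts.
    """
    if x_c <= 0 or x_0 <= 0 or x_ctrl <= 0:
        raise QuantifyError("growth rate needs positive cell counts")
    if x_ctrl <= x_0:
        raise QuantifyError("growth rate undefined: control did not grow (x_ctrl <= x_0)")
    return 2.0 ** (math.log2(x_c / x_0) / math.log2(x_ctrl / x_0)) - 1.0


@dataclass
class GrowthInputs:
    x_c: float
    x_0: float
    x_ctrl: float

    def gr(self) -> float:
        return growth_rate(self.x_c, self.x_0, self.x_ctrl)


@dataclass
class DoseResponseFit:
    ic50: float
    hill: float
    top: float
    bottom: float
    timepoint: float | None
    converged: bool
    rmse: float
    reason: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            if not (self.ic50 > 0):
                raise QuantifyError("converged fit must have ic50 > 0")
            if self.bottom > self.top:
                raise QuantifyError("converged fit must have bottom <= top")


def _logistic4(x, top, bottom, log_ic50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (x - log_ic50)))


def fit_dose_response(
    concentrations: Sequence[float],
    responses: Sequence[float],
    timepoint: float | None = None,
    min_span: float = 0.1,
    top_bounds: tuple[float, float] = (0.5, 1.5),
) -> DoseResponseFit:
    """Four-parameter logistic fit of normalized response vs log10
    concentration (uniform least squares on the normalized scale).

    Requires >= 4 distinct concentrations. A series whose response span
    is below ``min_span`` is reported unconverged with reason
    "no effect within tested range". Initialization and the IC50 bounds
    are data-relative, so rescaling concentration units rescales the
    fitted IC50 exactly.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape:
        raise QuantifyError("concentrations and responses differ in length")
    if np.unique(conc).size < 4:
        raise QuantifyError("dose-response fit needs >= 4 distinct concentrations")
    if np.any(conc <= 0):
        raise QuantifyError("concentrations must be > 0")

    span = float(resp.max() - resp.min())
    if span < min_span:
        return DoseResponseFit(
            ic50=float("nan"), hill=float("nan"),
            top=float(resp.mean()), bottom=float(resp.mean()),
            timepoint=timepoint, converged=False, rmse=0.0,
            reason="no effect within tested range",
        )

    x = np.log10(conc)
    order = np.argsort(x)
    x_s, r_s = x[order], resp[order]
    top0 = float(np.clip(r_s[:2].mean(), *top_bounds))
    bottom0 = float(np.clip(r_s[-2:].mean(), 0.0, top0))
    mid = 0.5 * (top0 + bottom0)
    log_ic50_0 = float(x_s[np.argmin(np.abs(r_s - mid))])
    p0 = (top0, bottom0, log_ic50_0, 1.0)
    bounds = (
        (top_bounds[0], 0.0, x.min() - 3.0, 0.1),
        (top_bounds[1], 1.5, x.max() + 3.0, 10.0),
    )
    try:
        popt, _ = curve_fit(_logistic4, x, resp, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        return DoseResponseFit(
            float("nan"), float("nan"), float("nan"), float("nan"),
            timepoint, False, float("nan"), reason=f"optimizer failed: {exc}",
        )
    top, bottom, log_ic50, hill = (float(v) for v in popt)
    pred = _logistic4(x, *popt)
    rmse = float(np.sqrt(np.mean((pred - resp) ** 2)))
    if bottom > top:
        return DoseResponseFit(
            float("nan"), hill, top, bottom, timepoint, False, rmse,
            reason="inverted fit (bottom > top)",
        )
    return DoseResponseFit(10.0**log_ic50, hill, top, bottom, timepoint, True, rmse)


@dataclass
class CompoundCertificate:
    """Per-compound flag report across cell lines, concentrations and
    timepoints. ``flagged_overall`` is true iff some phenotypic rule
    fires in every configured cell line."""

    compound: str
    entries: pd.DataFrame
    rule_results: dict
    flags: list[str]
    flagged_overall: bool
    cell_lines: list[str]
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "compound": self.compound,
            "cell_lines": self.cell_lines,
            "flags": self.flags,
            "flagged_overall": self.flagged_overall,
            "rule_results": self.rule_results,
            "notes": self.notes,
            "entries": self.entries.replace({np.nan: None}).to_dict(orient="records"),
        }


def flag_compound(
    compound: str,
    summary_table: pd.DataFrame,
    thresholds: dict[str, tuple[str, str, float]] | None = None,
    cell_lines: Sequence[str] | None = None,
    respect_low_count: bool = True,
) -> CompoundCertificate:
    """Evaluate the flagging rules for one compound.

    ``summary_table`` holds one row per (cell_line, concentration,
    timepoint) with the fraction columns named in the rules. A rule
    fires for a cell line if any of its rows exceeds the threshold in
    the rule's direction; a missing metric never fires. Rows with
    ``low_count_flag`` are ignored when ``respect_low_count``.
    """
    rules = thresholds or DEFAULT_FLAG_RULES
    df = summary_table[summary_table.get("compound", compound) == compound]
    if df.empty:
        df = summary_table
    panel = list(cell_lines) if cell_lines else sorted(df["cell_line"].dropna().unique())
    notes: list[str] = []
    available = set(df["cell_line"].dropna().unique())
    missing = [l for l in panel if l not in available]
    if missing:
        notes.append(f"incomplete-panel: missing cell lines {missing}")
    eval_lines = [l for l in panel if l in available]

    usable = df
    if respect_low_count and "low_count_flag" in df.columns:
        usable = df[~df["low_count_flag"].fillna(False).astype(bool)]

    rule_results: dict[str, dict[str, bool]] = {}
    for rule_id, (col, op, thr) in rules.items():
        per_line: dict[str, bool] = {}
        for line in eval_lines:
            rows = usable[usable["cell_line"] == line]
            if col not in rows.columns:
                per_line[line] = False
                continue
            vals = pd.to_numeric(rows[col], errors="coerce").dropna()
            if vals.empty:
                per_line[line] = False
            elif op == ">":
                per_line[line] = bool((vals > thr).any())
            else:
                per_line[line] = bool((vals < thr).any())
        rule_results[rule_id] = per_line

    flags = [
        rid for rid, per_line in rule_results.items()
        if eval_lines and all(per_line[l] for l in eval_lines)
    ]
    return CompoundCertificate(
        compound=compound,
        entries=df.reset_index(drop=True),
        rule_results=rule_results,
        flags=flags,
        flagged_overall=bool(flags),
        cell_lines=panel,
        notes=notes,
    )


def population_heatmap_table(
    summary_table: pd.DataFrame,
    metrics: Sequence[str],
    group_cols: Sequence[str] = ("compound", "timepoint"),
) -> pd.DataFrame:
    """Tidy long-format table (group x metric) for reporting; replicate
    rows are aggregated by arithmetic mean. No plotting here."""
    if summary_table.empty:
        raise QuantifyError("need at least one summary row")
    present = [m for m in metrics if m in summary_table.columns]
    agg = (
        summary_table.groupby(list(group_cols), dropna=False)[present]
        .mean()
        .reset_index()
    )
    long = agg.melt(id_vars=list(group_cols), value_vars=present,
                    var_name="metric", value_name="value")
    return long.sort_values([*group_cols, "metric"]).reset_index(drop=True)
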