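"""Z-score signatures, median cut-offs and COVID/HC ratio classification.

The signature analysis standardises each analyte to Z-scores, derives a
per-analyte reference cut-off as the median Z-score of the healthy
controls (pooled across trimesters, or trimester-matched), and summarises
each subgroup by the proportion of subjects strictly above the cut-off.
Proportions are categorised at the 50% mark (decreased / unaltered /
increased) and the %COVID/%HC ratio per trimester is binned into
decreased (<=0.3x), unaltered (0.4-2x) and increased (>=3x).

Default standardisation uses the combined HC+COVID population on raw
pg/mL, which puts both groups on one scale; with right-skewed data this
makes all HC median cut-offs negative, the pattern expected of serum
cytokines. HC-only reference and a log10 transform are available options.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, SubgroupKey, round_half_away

CATEGORY_DECREASED = "decreased"
CATEGORY_UNALTERED = "unaltered"
CATEGORY_INCREASED = "increased"
NOT_EVALUABLE = "not_evaluable"


@dataclass
class ZMatrix:
    """Sample x analyte Z-scores plus sample metadata.

    ``values`` is indexed by subject row labels and has one column per
    analyte; ``meta`` is aligned row-wise and carries subject_id, group and
    trimester. ``reference`` records which population defined the scale.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    reference: str
    transform: str

    def subgroup_rows(self, key: SubgroupKey) -> pd.Index:
        m = self.meta["group"] == key.group
        if key.trimester != "ALL":
            m &= self.meta["trimester"] == key.trimester
        return self.values.index[m.to_numpy()]


@dataclass
class CutoffSet:
    """Per-analyte reference cut-offs (median HC Z-score)."""

    values: dict[str, float]
    mode: str


@dataclass
class SignatureProfile:
    """Per-analyte proportion of a subgroup strictly above the cut-off."""

    subgroup: SubgroupKey
    table: pd.DataFrame  # index analyte; columns proportion_above, n_evaluated, category


@dataclass
class RatioProfile:
    """%COVID/%HC per analyte at one trimester, with display binning."""

    trimester: int | str
    table: pd.DataFrame  # index analyte; columns ratio, display_ratio, class


def compute_zscores(cohort: Cohort, reference: str = "combined",
                    transform: str = "raw") -> ZMatrix:
    """Standardise each analyte: z = (x - mean_ref) / sd_ref.

    ``reference`` is ``combined`` (HC+COVID, all trimesters) or ``HC_only``;
    ``transform`` is ``raw`` or ``log10`` (non-positive values become
    missing under log10, with a warning). The reference mean/SD (ddof=1)
    are computed on non-missing reference values; every sample is then
    scored on the same per-analyte scale.
    """
    wide = cohort.to_wide()
    meta = wide[["subject_id", "group", "trimester"]].copy()
    x = wide[list(cohort.panel.mediators)].astype(float)
    if transform == "log10":
        nonpos = (x <= 0).sum().sum()
        if nonpos:
            warnings.warn(f"{nonpos} non-positive concentration(s) set to "
                          "missing under log10 transform")
        x = np.log10(x.where(x > 0))
    elif transform != "raw":
        raise ValueError(f"transform must be 'raw' or 'log10', got {transform!r}")

    if reference == "combined":
        ref_rows = x
    elif reference == "HC_only":
        ref_rows = x[(meta["group"] == "HC").to_numpy()]
    else:
        raise ValueError(f"reference must be 'combined' or 'HC_only', got {reference!r}")

    counts = ref_rows.count()
    if (counts < 2).any():
        bad = list(counts.index[counts < 2])
        raise ValueError(f"reference population has <2 non-missing values for {bad}")
    mean = ref_rows.mean()
    sd = ref_rows.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"zero reference standard deviation for {bad}")
    z = (x - mean) / sd
    z.index = meta["subject_id"].to_numpy()
    meta.index = z.index
    return ZMatrix(values=z, meta=meta, reference=reference, transform=transform)


def derive_cutoffs(z: ZMatrix, mode: str = "global_HC",
                   trimester: int | None = None) -> CutoffSet:
    """Median HC Z-score per analyte, pooled (``global_HC``) or
    trimester-matched (``trimester_HC`` with a trimester argument)."""
    if mode == "global_HC":
        key = SubgroupKey("HC", "ALL")
        label = "global_HC"
    elif mode == "trimester_HC":
        if trimester not in (1, 2, 3):
            raise ValueError("trimester_HC mode needs trimester in {1,2,3}")
        key = SubgroupKey("HC", trimester)
        label = f"trimester_HC({trimester})"
    else:
        raise ValueError(f"mode must be 'global_HC' or 'trimester_HC', got {mode!r}")
    rows = z.subgroup_rows(key)
    if len(rows) == 0:
        raise ValueError(f"no HC samples for cut-off mode {label}")
    ref = z.values.loc[rows]
    medians = ref.median()  # even count -> mean of the two central values
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise ValueError(f"no non-missing HC values for {bad} in mode {label}")
    return CutoffSet(values=medians.to_dict(), mode=label)


def _categorise(proportion: float) -> str:
    if np.isnan(proportion):
        return NOT_EVALUABLE
    if proportion < 50:
        return CATEGORY_DECREASED
    if proportion > 50:
        return CATEGORY_INCREASED
    return CATEGORY_UNALTERED


def signature_proportions(z: ZMatrix, cutoffs: CutoffSet,
                          subgroup: SubgroupKey) -> SignatureProfile:
    """Proportion (%) of subgroup subjects strictly above each cut-off.

    Only non-missing values count towards ``n_evaluated``; an analyte with
    no evaluable subjects gets a missing proportion, flagged as
    ``not_evaluable``.
    """
    rows = z.subgroup_rows(subgroup)
    if len(rows) == 0:
        raise ValueError(f"subgroup {subgroup.label()} is empty")
    sub = z.values.loc[rows]
    records = {}
    for analyte in z.values.columns:
        cut = cutoffs.values[analyte]
        vals = sub[analyte].dropna()
        n = len(vals)
        prop = 100.0 * float((vals > cut).sum()) / n if n else float("nan")
        records[analyte] = {"proportion_above": prop, "n_evaluated": n,
                            "category": _categorise(prop)}
    table = pd.DataFrame.from_dict(records, orient="index")
    table.index.name = "analyte"
    return SignatureProfile(subgroup=subgroup, table=table)


def display_ratio(ratio: float) -> float:
    """Round a %COVID/%HC ratio for display: one decimal below 1, nearest
    integer (half away from zero) otherwise."""
    if np.isnan(ratio):
        return ratio
    if ratio < 1:
        return round_half_away(ratio * 10) / 10.0
    return float(round_half_away(ratio))


def classify_ratio(display: float) -> str:
    """Bin a display ratio: decreased <=0.3x, increased >=3x, else unaltered."""
    if np.isnan(display):
        return NOT_EVALUABLE
    if display <= 0.3:
        return CATEGORY_DECREASED
    if display >= 3:
        return CATEGORY_INCREASED
    return CATEGORY_UNALTERED


def covid_hc_ratio(p_covid: SignatureProfile, p_hc: SignatureProfile) -> RatioProfile:
    """%COVID/%HC per analyte for one trimester.

    Not evaluable when %HC is zero or either proportion is missing.
    """
    if p_covid.subgroup.trimester != p_hc.subgroup.trimester:
        raise ValueError(
            f"trimester mismatch: COVID {p_covid.subgroup.trimester} vs "
            f"HC {p_hc.subgroup.trimester}")
    if list(p_covid.table.index) != list(p_hc.table.index):
        raise ValueError("profiles do not share the same analyte set/order")
    rows = {}
    for analyte in p_covid.table.index:
        pc = p_covid.table.loc[analyte, "proportion_above"]
        ph = p_hc.table.loc[analyte, "proportion_above"]
        if np.isnan(pc) or np.isnan(ph) or ph == 0:
            rows[analyte] = {"ratio": float("nan"), "display_ratio": float("nan"),
                             "class": NOT_EVALUABLE}
        else:
            ratio = pc / ph
            disp = display_ratio(ratio)
            rows[analyte] = {"ratio": ratio, "display_ratio": disp,
                             "class": classify_ratio(disp)}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "analyte"
    return RatioProfile(trimester=p_covid.subgroup.trimester, table=table)


def signature_heatmap(profiles: list[SignatureProfile],
                      csv_path=None, figure_path=None) -> pd.DataFrame:
    """Assemble the analyte x subgroup proportion matrix (heatmap data).

    Rows follow panel display order (the order of the first profile's
    index); columns are subgroup labels. Missing proportions stay missing.
    Optionally writes the matrix as CSV and renders a diverging heatmap
    centred on 50% (blue below, red above).
    """
    if not profiles:
        raise ValueError("need at least one signature profile")
    matrix = pd.DataFrame(
        {p.subgroup.label(): p.table["proportion_above"] for p in profiles})
    matrix.index.name = "analyte"
    if csv_path is not None:
        matrix.to_csv(csv_path)
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(1.2 + 0.6 * len(matrix.columns), 8))
        im = ax.imshow(matrix.to_numpy(dtype=float), cmap="RdBu_r",
                       vmin=0, vmax=100, aspect="auto")
        ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=45,
                      ha="right")
        ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=7)
        fig.colorbar(im, ax=ax, label="% above cut-off")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return matrix
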