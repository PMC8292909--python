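"""TMT proteomics post-processing.

Reporter-ion channels are summed across all quantified proteins and
mean-normalized (equal-loading assumption).  Differential abundance between
the two groups (−Tet controls vs +Tet OTUD7A-depleted, 3 vs 3 replicates) is
a two-sided Welch t-test on log2 intensities with log2fc = log2(mean +Tet /
mean −Tet); significance thresholds are raw p < 0.05 and |log2fc| ≥ 0.5
(inclusive boundary — the published down-regulated list contains −0.5
exactly).  Overlap against external target lists and a second differential
study is classified into groups I–IV by sign concordance.

Sign convention: negative log2fc = lower abundance upon depletion (+Tet).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupDesign:
    """channel name -> group label; exactly two groups used for testing."""

    control: list[str]          # −Tet channels
    treatment: list[str]        # +Tet channels

    def __post_init__(self):
        if len(self.control) < 2 or len(self.treatment) < 2:
            raise ValueError("each group needs >= 2 channels")
        if set(self.control) & set(self.treatment):
            raise ValueError("channels cannot be in both groups")


def normalize_channels(m: pd.DataFrame) -> pd.DataFrame:
    """Scale each channel by (mean of all channel sums) / (that channel's sum)
    so every channel sums to the pre-normalization mean.  Idempotent; ratios
    between proteins within a channel are unchanged."""
    sums = m.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero-sum channel(s): {list(zero.index)}")
    return m * (sums.mean() / sums)


def differential_abundance(m: pd.DataFrame, design: GroupDesign,
                           equal_var: bool = False) -> pd.DataFrame:
    """Per-protein log2 fold change and two-sided t-test p-value.

    Proteins not quantified (NaN) in every design channel, or with a zero
    group mean, are flagged (``valid`` False) and excluded from thresholding.
    """
    cols = design.control + design.treatment
    missing = [c for c in cols if c not in m.columns]
    if missing:
        raise KeyError(f"channels not in matrix: {missing}")
    ctrl = m[design.control].to_numpy(dtype=float)
    trt = m[design.treatment].to_numpy(dtype=float)
    quantified = np.isfinite(ctrl).all(axis=1) & np.isfinite(trt).all(axis=1)
    mc, mt = np.nanmean(ctrl, axis=1), np.nanmean(trt, axis=1)
    ok = quantified & (mc > 0) & (mt > 0)
    lfc = np.full(len(m), np.nan)
    lfc[ok] = np.log2(mt[ok] / mc[ok])
    pvals = np.full(len(m), np.nan)
    if ok.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(np.log2(trt[ok]), np.log2(ctrl[ok]),
                                  axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue)
        p[~np.isfinite(p)] = 1.0  # identical values in both groups -> no evidence
        pvals[ok] = p
    return pd.DataFrame({"log2fc": lfc, "p_value": pvals, "valid": ok}, index=m.index)


def apply_thresholds(stats_df: pd.DataFrame, p_max: float = 0.05, lfc_cut: float = 0.5):
    """(down, up) index sets: p < p_max and log2fc ≤ −lfc_cut / ≥ +lfc_cut."""
    ok = stats_df["valid"] if "valid" in stats_df else pd.Series(True, index=stats_df.index)
    sig = ok & (stats_df["p_value"] < p_max)
    down = set(stats_df.index[sig & (stats_df["log2fc"] <= -lfc_cut)])
    up = set(stats_df.index[sig & (stats_df["log2fc"] >= lfc_cut)])
    return down, up


@dataclass
class OverlapReport:
    targets_in_both: list
    targets_down: list
    targets_up: list
    groups: dict = field(default_factory=dict)  # "I".."IV" -> id lists

    def to_json(self) -> str:
        return json.dumps({
            "n_in_both": len(self.targets_in_both),
            "n_down": len(self.targets_down),
            "n_up": len(self.targets_up),
            "targets_down": self.targets_down,
            "targets_up": self.targets_up,
            "groups": self.groups,
        }, indent=1)


def _norm_ids(ids):
    seen, out = set(), []
    for i in ids:
        key = str(i).strip().upper()
        if key and key not in seen:
            seen.add(key)
            out.append(key)
    return out


def overlap_with_targets(down: set, up: set, stats_df: pd.DataFrame, targets,
                         second_study: pd.DataFrame | None = None,
                         second_lfc_col: str = "log2fc") -> OverlapReport:
    """Overlap of significant sets with a target gene list (case-insensitive
    symbols, duplicates dropped), plus optional group I–IV classification
    against a second study's differential table:

        I   up here   / up there        III  up here   / down there
        II  down here / up there        IV   down here / down there
    """
    targets = _norm_ids(targets)
    down_u = {str(i).upper() for i in down}
    up_u = {str(i).upper() for i in up}
    measured = {str(i).upper() for i in stats_df.index}
    in_both = [t for t in targets if t in measured]
    report = OverlapReport(
        targets_in_both=in_both,
        targets_down=[t for t in targets if t in down_u],
        targets_up=[t for t in targets if t in up_u],
    )
    if second_study is not None:
        other = {str(i).upper(): v for i, v in second_study[second_lfc_col].items()}
        common_sig = sorted((down_u | up_u) & set(other))
        groups = {"I": [], "II": [], "III": [], "IV": []}
        for g in common_sig:
            here_up = g in up_u
            there_up = other[g] > 0
            key = {(True, True): "I", (False, True): "II",
                   (True, False): "III", (False, False): "IV"}[(here_up, there_up)]
            groups[key].append(g)
        report.groups = groups
    return report


# ---------------------------------------------------------------------------
# packaged published tables

def load_published_table(which: int) -> pd.DataFrame:
    """The published EWS–FLI1-target tables: 33 down-regulated (table 1) or
    6 up-regulated (table 2) proteins upon OTUD7A depletion, as gene symbol +
    log2 fold change."""
    name = {1: "table1.tsv", 2: "table2.tsv"}[which]
    ref = importlib.resources.files("pocketscreen.data").joinpath(name)
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t").set_index("gene")


def read_intensity_matrix(path, sep=None) -> pd.DataFrame:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)
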