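"""Mapping discriminative features back to brain regions.

Every feature in the optimal subset names either one ROI (degree, local
efficiency, clustering coefficient) or two (a shortest path between a
pair of ROIs). Counting how often each ROI appears across the subset
gives its frequency; regions are ranked by descending frequency — the
higher the frequency, the more discriminative (abnormal) the area.

The module ships the standard 90-region AAL parcellation label table
(left/right alternating, e.g. index 27 = REC.L, left gyrus rectus) and a
small Pearson chi-square utility for 2 x 2 demographic tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .graph_metrics import FeatureIndexEntry, FeatureIndexMap, METRIC_SHORTEST_PATH

#: Abbreviated AAL region names in standard atlas order (1-based atlas
#: indices 1..90; odd = left hemisphere, even = right).
AAL90_LABELS: tuple[str, ...] = (
    "PreCG.L", "PreCG.R", "SFGdor.L", "SFGdor.R", "ORBsup.L", "ORBsup.R",
    "MFG.L", "MFG.R", "ORBmid.L", "ORBmid.R", "IFGoperc.L", "IFGoperc.R",
    "IFGtriang.L", "IFGtriang.R", "ORBinf.L", "ORBinf.R", "ROL.L", "ROL.R",
    "SMA.L", "SMA.R", "OLF.L", "OLF.R", "SFGmed.L", "SFGmed.R",
    "ORBsupmed.L", "ORBsupmed.R", "REC.L", "REC.R", "INS.L", "INS.R",
    "ACG.L", "ACG.R", "DCG.L", "DCG.R", "PCG.L", "PCG.R", "HIP.L", "HIP.R",
    "PHG.L", "PHG.R", "AMYG.L", "AMYG.R", "CAL.L", "CAL.R", "CUN.L", "CUN.R",
    "LING.L", "LING.R", "SOG.L", "SOG.R", "MOG.L", "MOG.R", "IOG.L", "IOG.R",
    "FFG.L", "FFG.R", "PoCG.L", "PoCG.R", "SPG.L", "SPG.R", "IPL.L", "IPL.R",
    "SMG.L", "SMG.R", "ANG.L", "ANG.R", "PCUN.L", "PCUN.R", "PCL.L", "PCL.R",
    "CAU.L", "CAU.R", "PUT.L", "PUT.R", "PAL.L", "PAL.R", "THA.L", "THA.R",
    "HES.L", "HES.R", "STG.L", "STG.R", "TPOsup.L", "TPOsup.R", "MTG.L",
    "MTG.R", "TPOmid.L", "TPOmid.R", "ITG.L", "ITG.R",
)


def region_labels(n_regions: int) -> list[str]:
    """AAL abbreviations for 90 regions, generic ``ROI_<k>`` otherwise."""
    if n_regions == 90:
        return list(AAL90_LABELS)
    return [f"ROI_{k}" for k in range(n_regions)]


def feature_to_rois(feature_index: int, index_map: FeatureIndexMap) -> list[str]:
    """ROI label(s) behind one feature: one for nodal metrics, two for paths."""
    if not 0 <= feature_index < len(index_map):
        raise ValueError(f"feature index {feature_index} out of range [0, {len(index_map)})")
    entry: FeatureIndexEntry = index_map[feature_index]
    if entry.metric == METRIC_SHORTEST_PATH:
        return [entry.roi_a, entry.roi_b]
    return [entry.roi_a]


@dataclass
class RegionFrequencyTable:
    """Per-ROI appearance counts over a feature subset, ranked descending."""

    table: pd.DataFrame  # columns: rank, frequency, roi, atlas_index

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    @property
    def total(self) -> int:
        return int(self.table["frequency"].sum())


def region_frequencies(optimal_subset, index_map: FeatureIndexMap) -> RegionFrequencyTable:
    """Count ROI occurrences across a feature subset and rank regions.

    Pair (shortest-path) features count both endpoints once each, so the
    frequencies sum to #nodal features + 2 x #pair features. Ties rank by
    ascending atlas index.
    """
    subset = np.asarray(optimal_subset, dtype=int)
    if subset.size == 0:
        raise ValueError("feature subset is empty")
    counts = {lab: 0 for lab in index_map.region_labels}
    for idx in subset:
        for roi in feature_to_rois(int(idx), index_map):
            counts[roi] += 1
    df = pd.DataFrame({
        "roi": index_map.region_labels,
        "atlas_index": np.arange(1, len(index_map.region_labels) + 1),
        "frequency": [counts[lab] for lab in index_map.region_labels],
    })
    df = df.sort_values(
        ["frequency", "atlas_index"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return RegionFrequencyTable(table=df[["rank", "frequency", "roi", "atlas_index"]])


def chi_square_independence(table) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2 x 2 count table.

    No continuity correction is applied; 1 degree of freedom. Used for
    demographic group-balance checks (e.g. sex x diagnosis).
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2 x 2 table, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("all row and column margins must be positive")
    res = chi2_contingency(obs, correction=False)
    return float(res.statistic), float(res.pvalue)
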