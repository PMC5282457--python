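"""Densitometry ratio formulas for blot-based binding and uptake assays.

Band volumes come from phosphorimager quantification (arbitrary units).
Each lane carries an aptamer band and a U6 snoRNA loading-control band;
background is subtracted per band.  Three derived quantities:

* band ratio: background-corrected aptamer signal over U6 signal,
* relative enrichment: an aptamer's band ratio over the starting library's,
* internalized fraction: percent of bound aptamer protected from RNase,
  i.e. 100 x (ratio with RNase) / (ratio without RNase).

All three are invariant under rescaling every volume in a lane pair by a
common positive factor, so the arbitrary units cancel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = [
    "BandMeasurement",
    "LaneQuantification",
    "band_ratio",
    "relative_enrichment",
    "internalized_fraction",
    "quantify_lanes",
]


@dataclass(frozen=True)
class BandMeasurement:
    volume: float
    background: float

    def __post_init__(self) -> None:
        if self.volume < 0 or self.background < 0:
            raise ValueError("volume and background must be non-negative")

    @property
    def net(self) -> float:
        return self.volume - self.background


@dataclass(frozen=True)
class LaneQuantification:
    aptamer: BandMeasurement
    u6: BandMeasurement
    condition: str = ""


def band_ratio(lane: LaneQuantification) -> float:
    """(aptamer - background) / (U6 - background) for one lane.

    A non-positive U6 net volume means the loading control failed and is an
    error.  A negative aptamer net volume (signal below background) is
    returned as-is; reporting layers clamp it to zero.
    """
    u6_net = lane.u6.net
    if u6_net <= 0:
        raise ValueError(
            f"lane {lane.condition!r}: U6 net volume {u6_net} <= 0 (loading control failed)"
        )
    return lane.aptamer.net / u6_net


def relative_enrichment(aptamer_ratio: float, library_ratio: float) -> float:
    """Fold-enrichment of an aptamer's band ratio over the starting library's."""
    if library_ratio <= 0:
        raise ValueError(f"library ratio must be positive, got {library_ratio}")
    return aptamer_ratio / library_ratio


def internalized_fraction(rs_plus: LaneQuantification, rs_minus: LaneQuantification) -> float:
    """Percent of cell-bound aptamer protected from RNase treatment.

    100 x band_ratio(RNase-treated lane) / band_ratio(untreated lane).
    """
    denom = band_ratio(rs_minus)
    if denom <= 0:
        raise ValueError(f"untreated lane ratio {denom} <= 0; fraction undefined")
    return 100.0 * band_ratio(rs_plus) / denom


def quantify_lanes(
    table: pd.DataFrame,
    library_condition: Optional[str] = None,
) -> pd.DataFrame:
    """Per-lane report from a tidy band table.

    Expects columns ``lane, band, volume, background, condition`` with one
    ``aptamer`` and one ``u6`` band row per lane.  Negative net aptamer
    volumes are clamped to 0 in the report (signal below background means no
    detectable band) with a warning.  When ``library_condition`` names a
    lane, a ``relative_enrichment`` column against that lane is added.
    """
    required = {"lane", "band", "volume", "background", "condition"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for lane_id, grp in table.groupby("lane", sort=False):
        bands = {str(b).lower(): r for b, r in zip(grp["band"], grp.itertuples())}
        if "aptamer" not in bands or "u6" not in bands:
            raise ValueError(f"lane {lane_id!r} needs one 'aptamer' and one 'u6' band")
        lane = LaneQuantification(
            aptamer=BandMeasurement(bands["aptamer"].volume, bands["aptamer"].background),
            u6=BandMeasurement(bands["u6"].volume, bands["u6"].background),
            condition=str(bands["aptamer"].condition),
        )
        ratio = band_ratio(lane)
        if ratio < 0:
            warnings.warn(
                f"lane {lane_id!r}: aptamer signal below background, clamping ratio to 0"
            )
            ratio = 0.0
        rows.append({"lane": lane_id, "condition": lane.condition, "ratio": ratio})
    report = pd.DataFrame(rows)
    if library_condition is not None:
        lib = report.loc[report["condition"] == library_condition, "ratio"]
        if lib.empty:
            raise ValueError(f"no lane with condition {library_condition!r}")
        report["relative_enrichment"] = [
            relative_enrichment(r, float(lib.iloc[0])) for r in report["ratio"]
        ]
    return report
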