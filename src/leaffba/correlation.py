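"""Per-reaction correlation of flux with a scanned parameter.

For every reaction in a scan, the absolute Pearson correlation |r| between
its flux series and the parameter series is computed over the feasible
points.  Reactions with no flux change across the scan carry no
correlation information and are excluded.  Strength classes follow the
convention that |r| in [0.9, 1] is "strong"; the moderate/weak cut at 0.5
is a documented default, configurable per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Set, Tuple

import numpy as np

from .scenarios import ScanResult

__all__ = [
    "CorrelationTable",
    "correlate_scan",
    "classify_strength",
    "compare_strong_sets",
    "STRONG_BAND",
    "MODERATE_CUT",
]

#: |r| interval reported as strongly correlated (closed on both edges).
STRONG_BAND = (0.9, 1.0)
#: |r| at or above this (and below the strong band) is "moderate".
MODERATE_CUT = 0.5

#: Flux series with variance below this are treated as constant.
_CONSTANT_TOL = 1e-12


@dataclass
class CorrelationTable:
    """Absolute Pearson coefficients per reaction, constants set aside."""

    parameter_name: str
    entries: Dict[str, float] = field(default_factory=dict)
    excluded_constant: Set[str] = field(default_factory=set)


def correlate_scan(scan: ScanResult) -> CorrelationTable:
    """|Pearson r| of each reaction's flux against the scan parameter.

    Only feasible points enter (infeasible points are dropped pairwise);
    at least 3 feasible points are required.  Zero-variance flux series go
    to ``excluded_constant``.
    """
    frame = scan.flux_frame()
    if len(frame) < 3:
        raise ValueError(f"need >= 3 feasible scan points, got {len(frame)}")
    x = frame.index.to_numpy(dtype=float)
    xc = x - x.mean()
    x_ss = float(xc @ xc)
    table = CorrelationTable(parameter_name=scan.parameter_name)
    values = frame.to_numpy(dtype=float)
    centered = values - values.mean(axis=0)
    ss = (centered**2).sum(axis=0)
    for j, rid in enumerate(frame.columns):
        if ss[j] < _CONSTANT_TOL:
            table.excluded_constant.add(rid)
            continue
        r = float(xc @ centered[:, j]) / np.sqrt(x_ss * ss[j])
        table.entries[rid] = min(abs(r), 1.0)
    return table


def classify_strength(
    table: CorrelationTable,
    strong_band: Tuple[float, float] = STRONG_BAND,
    moderate_cut: float = MODERATE_CUT,
) -> Dict[str, str]:
    """Map each correlated reaction to strong / moderate / weak.

    Strong iff |r| is inside ``strong_band`` (closed lower edge); moderate
    iff ``moderate_cut <= |r| < strong_band[0]``; weak otherwise.
    """
    lo, hi = strong_band
    out: Dict[str, str] = {}
    for rid, r in table.entries.items():
        if lo <= r <= hi:
            out[rid] = "strong"
        elif moderate_cut <= r < lo:
            out[rid] = "moderate"
        else:
            out[rid] = "weak"
    return out


def compare_strong_sets(
    table_a: CorrelationTable,
    table_b: CorrelationTable,
    strong_band: Tuple[float, float] = STRONG_BAND,
) -> Tuple[Set[str], Set[str], Set[str]]:
    """Partition strongly correlated reactions across two scans.

    Returns ``(only_a, only_b, both)`` — e.g. reactions tied to the
    RuBisCO ratio only, to light only, or to both.
    """
    strong_a = {r for r, c in classify_strength(table_a, strong_band).items() if c == "strong"}
    strong_b = {r for r, c in classify_strength(table_b, strong_band).items() if c == "strong"}
    return strong_a - strong_b, strong_b - strong_a, strong_a & strong_b
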