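"""Per-animal relative changes and between-region comparison statistics.

Each animal contributes one capillary-flow parameter set (MTV, MTT,
CTTH) per region (activated HLS1 vs non-activated CTRL) and condition
(rest vs stimulation).  The per-animal relative change
Δx = 100·(x_stim − x_rest)/x_rest is compared between regions with a
two-tailed two-sample Student t-test (pooled variance by default,
Welch optional); p < 0.05 is flagged *, p < 0.01 **.  No
multiple-testing correction is applied across the three parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PARAMETERS",
    "REGIONS",
    "CONDITIONS",
    "AnimalRecord",
    "RelativeChange",
    "RegionComparison",
    "relative_change",
    "compare_regions",
    "summarize_table",
    "records_from_csv",
    "simulate_change_study",
]

PARAMETERS = ("mtv", "mtt", "ctth")
REGIONS = ("HLS1", "CTRL")
CONDITIONS = ("rest", "stimulation")


@dataclass(frozen=True)
class AnimalRecord:
    """One animal × region × condition parameter set."""

    animal_id: str
    region: str  # HLS1 | CTRL
    condition: str  # rest | stimulation
    mtv: float  # mm/s
    mtt: float  # s
    ctth: float  # s

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        for p in PARAMETERS:
            if getattr(self, p) <= 0:
                raise ValueError(f"{p} must be positive")


@dataclass(frozen=True)
class RelativeChange:
    """Percent change rest → stimulation, per animal per region."""

    animal_id: str
    region: str
    mtv: float
    mtt: float
    ctth: float


@dataclass
class RegionComparison:
    """Two-tailed two-sample t-test on per-animal Δ between regions."""

    parameter: str
    mean: dict[str, float]  # region -> group mean Δ (%)
    std: dict[str, float]  # region -> group std Δ (%)
    n: dict[str, int]
    t_statistic: float
    p_value: float
    equal_var: bool

    @property
    def stars(self) -> str:
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return "ns"


def relative_change(rest: AnimalRecord, stim: AnimalRecord) -> RelativeChange:
    """Δx = 100·(x_stim − x_rest)/x_rest for each flow parameter."""
    if rest.animal_id != stim.animal_id or rest.region != stim.region:
        raise ValueError("rest/stimulation records must share animal and region")
    if rest.condition != "rest" or stim.condition != "stimulation":
        raise ValueError("pass (rest, stimulation) records in that order")
    deltas = {p: 100.0 * (getattr(stim, p) - getattr(rest, p)) / getattr(rest, p)
              for p in PARAMETERS}
    return RelativeChange(rest.animal_id, rest.region, **deltas)


def compare_regions(
    changes: Iterable[RelativeChange],
    parameter: str,
    equal_var: bool = True,
) -> RegionComparison:
    """Student t-test (two-tailed) of per-animal Δ, HLS1 vs CTRL.

    Pooled-variance (classical Student) by default; ``equal_var=False``
    selects Welch.  Degenerate identical groups yield t = 0, p = 1.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"parameter must be one of {PARAMETERS}")
    groups = {r: [] for r in REGIONS}
    for c in changes:
        groups[c.region].append(getattr(c, parameter))
    a, b = (np.asarray(groups[r], dtype=float) for r in REGIONS)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 animals per region")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    return RegionComparison(
        parameter,
        mean={"HLS1": float(a.mean()), "CTRL": float(b.mean())},
        std={"HLS1": float(a.std(ddof=1)), "CTRL": float(b.std(ddof=1))},
        n={"HLS1": int(a.size), "CTRL": int(b.size)},
        t_statistic=t, p_value=p, equal_var=equal_var)


def summarize_table(records: Sequence[AnimalRecord]) -> pd.DataFrame:
    """Mean ± std per region × condition × parameter.

    Rows are MTV/MTT/CTTH; columns a (region, condition, {mean, std, n})
    MultiIndex shaped like a flow-parameter report table.  Missing
    design cells raise with an explicit list.
    """
    df = pd.DataFrame([vars(r) for r in records])
    if df.empty:
        raise ValueError("no records")
    missing = []
    for region in REGIONS:
        for cond in CONDITIONS:
            if df[(df.region == region) & (df.condition == cond)].empty:
                missing.append((region, cond))
    if missing:
        raise ValueError(f"missing design cells: {missing}")
    out = {}
    for region in REGIONS:
        for cond in CONDITIONS:
            sub = df[(df.region == region) & (df.condition == cond)]
            label = cond.capitalize()
            for p in PARAMETERS:
                vals = sub[p].to_numpy(dtype=float)
                std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
                out.setdefault((region, label, "mean"), {})[p.upper()] = vals.mean()
                out.setdefault((region, label, "std"), {})[p.upper()] = std
                out.setdefault((region, label, "n"), {})[p.upper()] = vals.size
    table = pd.DataFrame(out)
    table.columns = pd.MultiIndex.from_tuples(table.columns,
                                              names=["region", "condition",
                                                     "stat"])
    return table.loc[["MTV", "MTT", "CTTH"]]


def records_from_csv(path) -> list[AnimalRecord]:
    """Load AnimalRecords from CSV with columns
    animal_id, region, condition, mtv_mm_s, mtt_s, ctth_s."""
    df = pd.read_csv(path)
    return [AnimalRecord(str(r.animal_id), r.region, r.condition,
                         float(r.mtv_mm_s), float(r.mtt_s), float(r.ctth_s))
            for r in df.itertuples()]


def simulate_change_study(
    mean_hls1: float,
    mean_ctrl: float,
    std: float,
    n_animals: int = 12,
    seed: int = 0,
) -> list[RelativeChange]:
    """Draw per-animal Δ values (%) for one parameter in both regions.

    Normal per-animal relative changes with region-specific means and a
    shared std emulate a two-region activation study at printed effect
    sizes; other parameters are filled with the same draw (only the
    requested one is meaningful downstream).
    """
    rng = np.random.default_rng(seed)
    changes = []
    for region, mu in (("HLS1", mean_hls1), ("CTRL", mean_ctrl)):
        draws = rng.normal(mu, std, size=n_animals)
        for i, d in enumerate(draws):
            changes.append(RelativeChange(f"a{i:02d}", region,
                                          mtv=d, mtt=d, ctth=d))
    return changes
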