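"""Group comparisons: Mann-Whitney U on Py per temperature, the
two-sample t-test on time-normalized drip loss, and summary tables.

The per-temperature comparison mirrors the experiment's layout: two
independent groups (fast = water-bath thawed, slow = air thawed) of ten
samples each, one Py value per sample per 0.5 degC step from 0 to 4 degC
plus a "next day" measurement after >16 h of chilled storage.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import DripLossRecord

NEXT_DAY_LABEL = "next_day"

#: combined-n threshold below which the exact MWU null is enumerated
EXACT_MWU_MAX_N = 12


def _u_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(U_a, U_b) with midrank tie handling."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a, n_b = len(a), len(b)
    u_a = float(np.sum(ranks[:n_a]) - n_a * (n_a + 1) / 2.0)
    return u_a, n_a * n_b - u_a


def mann_whitney_u(a, b, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U, p)`` with U = min(Ua, Ub).

    method
        ``"exact"``   enumerate all C(n_a + n_b, n_a) group assignments of
        the pooled midranks; the two-sided p-value is the null probability
        of a U at least as far from its mean ``n_a n_b / 2`` as observed
        (well defined with ties; equals the usual 2*min(cdf, sf) when
        there are none).
        ``"normal"``  tie-corrected normal approximation with a 0.5
        continuity correction.
        ``"auto"``    exact when ``n_a + n_b <= 12``, else normal.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method not in ("exact", "normal", "auto"):
        raise ValueError(f"unknown method {method!r}")
    n_a, n_b = a.size, b.size
    u_a, u_b = _u_statistic(a, b)
    u_min = min(u_a, u_b)
    if method == "auto":
        method = "exact" if n_a + n_b <= EXACT_MWU_MAX_N else "normal"

    mu = n_a * n_b / 2.0
    if method == "exact":
        ranks = sps.rankdata(np.concatenate([a, b]))
        obs_dev = abs(u_a - mu)
        rank_offset = n_a * (n_a + 1) / 2.0
        hits = total = 0
        for combo in itertools.combinations(range(n_a + n_b), n_a):
            u = ranks[list(combo)].sum() - rank_offset
            hits += abs(u - mu) >= obs_dev - 1e-12
            total += 1
        return u_min, hits / total

    # tie-corrected normal approximation, continuity-corrected
    pooled = np.concatenate([a, b])
    n = n_a + n_b
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma_sq = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if sigma_sq <= 0:  # all values tied
        return u_min, 1.0
    z = (u_min - mu + 0.5) / math.sqrt(sigma_sq)  # u_min <= mu by construction
    p = min(1.0, 2.0 * sps.norm.cdf(z))
    return u_min, p


def two_sample_t(a, b, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test (Welch by default); returns ``(t, p)``.

    Both groups constant and equal means -> ``(0, 1)`` by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return math.inf if np.mean(a) > np.mean(b) else -math.inf, 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def drip_loss_percent(record: DripLossRecord, normalize_hours: float | None = None) -> float:
    """Drip loss as percent of initial weight, optionally rescaled linearly
    to a common storage duration (samples were weighed after 16-26 h)."""
    loss = 100.0 * (record.initial_weight_g - record.final_weight_g) / record.initial_weight_g
    if normalize_hours is None:
        return loss
    if record.storage_hours <= 0:
        raise ValueError("storage_hours must be positive for normalization")
    return loss * (normalize_hours / record.storage_hours)


# ---------------------------------------------------------------------------
# summary tables


@dataclass(frozen=True)
class GroupSummary:
    count: int
    median: float
    mean: float
    sd: float
    iqr: float

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError("cannot summarize an empty group")
        q1, q3 = np.percentile(v, [25, 75])  # linear-interpolation quantiles
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        return cls(int(v.size), float(np.median(v)), float(np.mean(v)), sd, float(q3 - q1))


@dataclass(frozen=True)
class ComparisonRow:
    temperature_label: str
    fast: GroupSummary | None
    slow: GroupSummary | None
    p_value: float | None
    flagged: bool = False


def comparison_table(
    py_by_group_and_temperature: Mapping[str, Mapping], temperatures: Sequence[float]
) -> list[ComparisonRow]:
    """Per-temperature fast-vs-slow comparison rows.

    ``py_by_group_and_temperature`` maps group ("fast_thaw"/"slow_thaw")
    to {temperature label: Py values}; labels are the temperatures plus
    ``"next_day"``.  One row per temperature plus a next-day row; a row
    with a missing or empty cell is emitted flagged, without a p-value.
    """
    fast = py_by_group_and_temperature.get("fast_thaw", {})
    slow = py_by_group_and_temperature.get("slow_thaw", {})
    labels = [_format_temperature(t) for t in temperatures] + [NEXT_DAY_LABEL]
    rows: list[ComparisonRow] = []
    for label in labels:
        va = np.asarray(fast.get(label, []), dtype=float)
        vb = np.asarray(slow.get(label, []), dtype=float)
        if va.size == 0 or vb.size == 0:
            rows.append(
                ComparisonRow(
                    label,
                    GroupSummary.from_values(va) if va.size else None,
                    GroupSummary.from_values(vb) if vb.size else None,
                    None,
                    flagged=True,
                )
            )
            continue
        _, p = mann_whitney_u(va, vb, method="auto")
        rows.append(
            ComparisonRow(
                label, GroupSummary.from_values(va), GroupSummary.from_values(vb), float(p)
            )
        )
    return rows


def _format_temperature(t) -> str:
    if isinstance(t, str):
        return t
    return f"{float(t):g}"


def comparison_rows_to_frame(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    """Long-format table (one line per temperature x group) with the MWU
    p-value on each line and a clearly-labelled Holm-adjusted column added
    as an extension beyond the unadjusted per-temperature tests."""
    ps = [r.p_value for r in rows if r.p_value is not None]
    holm = {}
    if ps:
        adjusted = multipletests(ps, method="holm")[1]
        holm = dict(zip([r.temperature_label for r in rows if r.p_value is not None], adjusted))
    recs = []
    for r in rows:
        for group, summ in (("Fast thaw", r.fast), ("Slow thaw", r.slow)):
            recs.append(
                {
                    "Temperature": r.temperature_label,
                    "Group": group,
                    "Count": None if summ is None else summ.count,
                    "Median": None if summ is None else summ.median,
                    "Mean": None if summ is None else summ.mean,
                    "SD": None if summ is None else summ.sd,
                    "IQR": None if summ is None else summ.iqr,
                    "p_value": r.p_value,
                    "p_holm_extension": holm.get(r.temperature_label),
                }
            )
    return pd.DataFrame(recs)


def py_mapping_from_fits(fits: pd.DataFrame, temperatures: Sequence[float]) -> dict:
    """Build the comparison_table input mapping from a fit_cohort frame.

    Each (group, temperature) cell collects the fitted Py of measurements
    whose temperature is nearest that scheduled value (within 0.25 degC);
    next-day measurements go to the ``"next_day"`` cell.
    """
    out: dict[str, dict[str, list[float]]] = {"fast_thaw": {}, "slow_thaw": {}}
    df = fits[fits["treatment"].isin(("fast_thaw", "slow_thaw"))]
    for _, row in df.iterrows():
        group = row["treatment"]
        if row["next_day"]:
            label = NEXT_DAY_LABEL
        else:
            nearest = min(temperatures, key=lambda t: abs(row["temperature_C"] - t))
            if abs(row["temperature_C"] - nearest) > 0.25:
                continue
            label = _format_temperature(nearest)
        out[group].setdefault(label, []).append(float(row["Py"]))
    return out
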