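"""Nitrogen-efficiency statistics and treatment-mean separation.

Implements the standard fertilizer-efficiency indices for a pot
experiment with a zero-N control:

    NUE (%)        = (AN - AN0) / SN * 100      nitrogen use efficiency
    NAE (kg kg-1)  = (GN - GN0) / SN            agronomic efficiency
    NPE (kg kg-1)  = (YN - YN0) / (AN - AN0)    physiological efficiency

where AN / AN0 are accumulated plant N uptake with and without
fertilizer, SN the fertilizer N dose, GN / GN0 grain dry weight and
YN / YN0 yield.  Percent changes versus a reference treatment are
reported rounded half-up to one decimal, matching agronomic reporting
conventions; raw values are retained alongside.

Treatment tables are compared by one-way ANOVA followed by Duncan's
multiple range test with a compact letter display.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats


def nue(an: float, an0: float, sn: float) -> float:
    """Nitrogen use efficiency in percent: (AN - AN0)/SN * 100."""
    if sn <= 0:
        raise ValueError("fertilizer N dose SN must be positive")
    return (an - an0) / sn * 100.0


def nae(gn: float, gn0: float, sn: float) -> float:
    """Agronomic efficiency, kg grain per kg fertilizer N: (GN - GN0)/SN."""
    if sn <= 0:
        raise ValueError("fertilizer N dose SN must be positive")
    return (gn - gn0) / sn


def npe(yn: float, yn0: float, an: float, an0: float) -> float | None:
    """Physiological efficiency (YN - YN0)/(AN - AN0).

    Returns None (missing) when AN == AN0, where the index is undefined.
    """
    if an == an0:
        return None
    return (yn - yn0) / (an - an0)


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero, as printed agronomic tables do (banker's
    rounding would turn 22.15 into 22.2 either way, but 22.25 into 22.2)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def percent_change(value: float, reference: float, decimals: int = 1) -> float:
    """(value - reference)/reference * 100, rounded half-up to ``decimals``."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return round_half_up((value - reference) / reference * 100.0, decimals)


def efficiency_table(
    agronomic: pd.DataFrame,
    control: str = "control",
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-treatment NUE/NAE/NPE from a replicate-level agronomic table.

    ``agronomic`` needs columns ``treatment``, ``grain_yield``, ``biomass``,
    ``n_uptake`` and ``n_dose``; the zero-N ``control`` treatment supplies
    AN0/GN0/YN0 as its means.  When ``reference`` is given, a
    ``pct_change_vs_reference`` column compares each index (computed on
    raw means, rounded only for display) against that treatment.
    """
    required = {"treatment", "grain_yield", "biomass", "n_uptake", "n_dose"}
    missing = required - set(agronomic.columns)
    if missing:
        raise ValueError(f"agronomic table missing columns: {sorted(missing)}")
    means = agronomic.groupby("treatment").mean(numeric_only=True)
    if control not in means.index:
        raise ValueError(f"control treatment {control!r} not present")
    an0 = means.loc[control, "n_uptake"]
    gn0 = means.loc[control, "grain_yield"]
    rows = {}
    for treatment, row in means.iterrows():
        if treatment == control:
            continue
        sn = row["n_dose"]
        if sn <= 0:
            continue  # no fertilizer N (e.g. organic-synergist-only treatment)
        rows[treatment] = {
            "NUE": nue(row["n_uptake"], an0, sn),
            "NAE": nae(row["grain_yield"], gn0, sn),
            "NPE": npe(row["grain_yield"], gn0, row["n_uptake"], an0),
        }
    out = pd.DataFrame(rows).T
    if reference is not None:
        if reference not in out.index:
            raise ValueError(f"reference treatment {reference!r} not fertilized/present")
        for index_name in ("NUE", "NAE", "NPE"):
            ref_value = out.loc[reference, index_name]
            out[f"{index_name}_change_vs_{reference}"] = [
                percent_change(v, ref_value)
                if t != reference and v is not None and ref_value not in (None, 0)
                else (0.0 if t == reference else np.nan)
                for t, v in out[index_name].items()
            ]
    return out


@dataclass(frozen=True)
class DuncanResult:
    """One-way ANOVA plus Duncan's multiple-range letter display.

    ``table`` has one row per group with its mean, n and letters; groups
    sharing a letter are not separated at the chosen alpha.
    """

    f_statistic: float
    p_value: float
    mse: float
    df_error: int
    table: pd.DataFrame


def _duncan_critical_range(alpha: float, span: int, df_error: int, mse: float, n_h: float) -> float:
    # protection level for a span of p ordered means
    alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
    q = stats.studentized_range.ppf(1.0 - alpha_p, span, df_error)
    return float(q * np.sqrt(mse / n_h))


def anova_duncan(values, groups, alpha: float = 0.05) -> DuncanResult:
    """One-way ANOVA with Duncan's multiple range test.

    Groups are ordered by mean; the critical range for a span of p means is
    q*(alpha_p, p, df_error) * sqrt(MSE / n_h) with protection level
    alpha_p = 1 - (1 - alpha)^(p-1) and n_h the harmonic mean group size.
    Letters are assigned so that any two groups sharing a letter are not
    separated.  Critical values come from the studentized range
    distribution, not from printed tables.
    """
    frame = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    sizes = frame.groupby("group").size()
    if len(sizes) < 2:
        raise ValueError("need >= 2 groups")
    if (sizes < 2).any():
        raise ValueError("every group needs >= 2 replicates")
    arrays = [g["value"].to_numpy() for _, g in frame.groupby("group")]
    f_stat, p_value = stats.f_oneway(*arrays)
    n_total = len(frame)
    k = len(sizes)
    df_error = n_total - k
    group_means = frame.groupby("group")["value"].mean()
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    mse = sse / df_error
    n_h = k / (1.0 / sizes).sum()

    order = group_means.sort_values(ascending=False)
    names = list(order.index)
    means = order.to_numpy()

    def separated(i: int, j: int) -> bool:
        # i < j in descending-mean order; span = j - i + 1
        if mse == 0:
            return means[i] != means[j]
        cr = _duncan_critical_range(alpha, j - i + 1, df_error, mse, n_h)
        return means[i] - means[j] >= cr

    # maximal runs of mutually non-separated consecutive groups -> letters
    runs = []
    i = 0
    while i < k:
        j = i
        while j + 1 < k and not separated(i, j + 1):
            j += 1
        runs.append((i, j))
        i += 1
    # keep only maximal runs
    maximal = [r for r in runs if not any(o[0] <= r[0] and r[1] <= o[1] and o != r for o in runs)]
    letters = {name: "" for name in names}
    for letter_index, (start, end) in enumerate(maximal):
        letter = chr(ord("a") + letter_index)
        for idx in range(start, end + 1):
            letters[names[idx]] += letter
    table = pd.DataFrame(
        {
            "mean": order,
            "n": sizes.reindex(names),
            "letters": pd.Series(letters).reindex(names),
        }
    )
    return DuncanResult(float(f_stat), float(p_value), float(mse), int(df_error), table)
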