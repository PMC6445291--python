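"""Depth- and region-resolved model comparison and feature-preference maps.

The cortical-depth grid carries 9 depths (0.1 deep .. 0.9 superficial) and
a myelin-related-contrast (MRC) value per grid point; the half of the grid
with higher MRC is primary auditory cortex (PAC), the rest non-PAC.
Identification scores are aggregated into deep {0.1-0.3}, middle
{0.4-0.6} and superficial {0.7-0.9} bins per analysis unit (hemisphere),
compared between models by a two-way repeated-measures ANOVA
(Model x Cortical Depth, after Fisher transformation) with per-depth
one-sided post-hoc paired t-tests (Bonferroni x3), and summarised as the
modulation-minus-frequency difference profile.  Preference maps assign
each grid point the best frequency, temporal rate and spectral scale of
its trained modulation-model weights (argmax of the weight marginals);
rate and scale maps are compared across units via a Wilcoxon signed-rank
test on Fisher-transformed per-unit map correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .identification import fisher_transform

DEPTH_BINS = {"deep": (0.1, 0.2, 0.3), "middle": (0.4, 0.5, 0.6),
              "superficial": (0.7, 0.8, 0.9)}
BIN_ORDER = ("deep", "middle", "superficial")

__all__ = [
    "DEPTH_BINS",
    "BIN_ORDER",
    "DepthProfile",
    "PreferenceMap",
    "AnovaReport",
    "split_pac",
    "depth_bin_scores",
    "rm_anova_model_by_depth",
    "posthoc_by_depth",
    "build_preference_maps",
    "map_correlation_test",
]


@dataclass
class DepthProfile:
    """Region x depth-bin x model score means over analysis units."""

    table: pd.DataFrame  # columns: region, depth_bin, model, mean, sem, n
    per_unit: pd.DataFrame  # columns: unit, region, depth_bin, model, score
    difference: pd.DataFrame  # modulation - frequency per (region, depth_bin)


@dataclass
class PreferenceMap:
    """Per grid point argmax-weight acoustic preferences."""

    best_frequency_hz: np.ndarray
    best_rate_hz: np.ndarray
    best_scale_cpo: np.ndarray
    tie_flags: np.ndarray
    undefined: np.ndarray


@dataclass
class AnovaReport:
    """Two-way repeated-measures ANOVA table."""

    table: pd.DataFrame  # rows: Model, Depth, Model x Depth

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    def F(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])


def split_pac(mrc: np.ndarray) -> np.ndarray:
    """PAC mask: the half of the grid points with the highest MRC.

    Exact half split (floor(n/2) points for odd n); ties at the median are
    broken by stable point index.  All-equal MRC emits a warning.
    """
    mrc = np.asarray(mrc, dtype=float)
    finite = np.isfinite(mrc)
    if mrc.size < 2 or not finite.any():
        raise ValueError("need >= 2 grid points with finite MRC")
    if np.nanmin(mrc) == np.nanmax(mrc):
        warnings.warn("all MRC values equal; PAC split falls back to point order")
    key = np.where(finite, -mrc, np.inf)
    order = np.argsort(key, kind="stable")
    mask = np.zeros(mrc.size, dtype=bool)
    mask[order[: mrc.size // 2]] = True
    return mask


def _bin_of_depth(depth: float) -> str:
    for name, levels in DEPTH_BINS.items():
        if np.any(np.isclose(depth, levels)):
            return name
    raise ValueError(f"depth {depth} is not one of the 9 canonical levels")


def depth_bin_scores(scores: pd.DataFrame) -> DepthProfile:
    """Aggregate per-depth-level scores into deep/middle/superficial bins.

    ``scores`` is tidy with columns unit, region, depth, model, score (one
    row per unit x region x depth level x model).  Scores are averaged
    over the 3 levels of each bin per unit; an empty (region, depth bin,
    model) cell raises with the offending cell named.
    """
    required = {"unit", "region", "depth", "model", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores must have columns {sorted(required)}")
    df = scores.copy()
    df["depth_bin"] = df["depth"].map(_bin_of_depth)
    per_unit = (
        df.groupby(["unit", "region", "depth_bin", "model"], observed=True)["score"]
        .mean()
        .reset_index()
    )
    regions = sorted(df["region"].unique())
    models = sorted(df["model"].unique())
    for reg in regions:
        for b in BIN_ORDER:
            for m in models:
                cell = per_unit[
                    (per_unit.region == reg)
                    & (per_unit.depth_bin == b)
                    & (per_unit.model == m)
                ]
                if cell.empty:
                    raise ValueError(f"empty cell: region={reg}, bin={b}, model={m}")
    table = (
        per_unit.groupby(["region", "depth_bin", "model"], observed=True)["score"]
        .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="count")
        .reset_index()
    )
    diff_rows = []
    if {"modulation", "frequency"}.issubset(models):
        wide = per_unit.pivot_table(
            index=["unit", "region", "depth_bin"], columns="model", values="score"
        ).reset_index()
        wide["difference"] = wide["modulation"] - wide["frequency"]
        diff_rows = (
            wide.groupby(["region", "depth_bin"], observed=True)["difference"]
            .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)))
            .reset_index()
        )
    difference = (
        pd.DataFrame(diff_rows)
        if len(diff_rows)
        else pd.DataFrame(columns=["region", "depth_bin", "mean", "sem"])
    )
    return DepthProfile(table=table, per_unit=per_unit, difference=difference)


def _rm_anova_arrays(y: np.ndarray) -> pd.DataFrame:
    """Classical two-way within-subject ANOVA on y (units, A, B)."""
    n, a, b = y.shape
    m = y.mean()
    m_i = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ia = y.mean(axis=2)
    m_ib = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - m) ** 2)
    ss_as = b * np.sum((m_ia - m_a[None, :] - m_i[:, None] + m) ** 2)
    ss_b = n * a * np.sum((m_b - m) ** 2)
    ss_bs = a * np.sum((m_ib - m_b[None, :] - m_i[:, None] + m) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2)
    resid = (
        y
        - m_ia[:, :, None]
        - m_ib[:, None, :]
        - m_ab[None, :, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_i[:, None, None]
        - m
    )
    ss_abs = np.sum(resid**2)

    rows = []
    for name, ss, df1, ss_err, df2 in [
        ("Model", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        ("Depth", ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        ("Model x Depth", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ]:
        ms, ms_err = ss / df1, ss_err / df2
        f = ms / ms_err if ms_err > 0 else np.inf
        rows.append(
            {
                "effect": name,
                "SS": ss,
                "df1": df1,
                "SS_error": ss_err,
                "df2": df2,
                "F": f,
                "p": float(stats.f.sf(f, df1, df2)),
            }
        )
    return pd.DataFrame(rows).set_index("effect")


def rm_anova_model_by_depth(
    scores: pd.DataFrame, fisher: bool = True
) -> AnovaReport:
    """Two-way RM ANOVA, factors Model (2) x Cortical Depth (3 bins).

    ``scores`` is tidy with columns unit, model, depth_bin, score; the
    Fisher transform atanh(2P - 1) is applied first by default.  Requires
    a balanced, complete table with >= 3 units.
    """
    required = {"unit", "model", "depth_bin", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores must have columns {sorted(required)}")
    units = sorted(scores["unit"].unique())
    models = sorted(scores["model"].unique())
    bins = [b for b in BIN_ORDER if b in set(scores["depth_bin"])]
    if len(units) < 3:
        raise ValueError("need >= 3 analysis units for the RM ANOVA")
    pivot = scores.pivot_table(
        index="unit", columns=["model", "depth_bin"], values="score"
    )
    if pivot.isna().any().any() or pivot.shape[1] != len(models) * len(bins):
        raise ValueError("RM ANOVA requires a complete balanced table")
    y = np.empty((len(units), len(models), len(bins)))
    for ai, mdl in enumerate(models):
        for bi, b in enumerate(bins):
            y[:, ai, bi] = pivot[(mdl, b)].loc[units].to_numpy()
    if fisher:
        y = fisher_transform(y)
    return AnovaReport(table=_rm_anova_arrays(y))


def posthoc_by_depth(
    scores: pd.DataFrame,
    correction: int = 3,
    fisher: bool = True,
) -> pd.DataFrame:
    """One-sided paired t-tests (modulation > frequency) per depth bin.

    Bonferroni-corrected by ``correction`` (default 3, one per bin).
    ``scores`` is tidy per-unit with columns unit, model, depth_bin, score.
    """
    rows = []
    for b in BIN_ORDER:
        sub = scores[scores["depth_bin"] == b]
        if sub.empty:
            continue
        wide = sub.pivot_table(index="unit", columns="model", values="score")
        if len(wide) < 2:
            raise ValueError(f"depth bin {b}: need >= 2 paired units")
        a = wide["modulation"].to_numpy()
        f = wide["frequency"].to_numpy()
        if fisher:
            a, f = fisher_transform(a), fisher_transform(f)
        res = stats.ttest_rel(a, f, alternative="greater")
        p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
        t = 0.0 if np.isnan(res.statistic) else float(res.statistic)
        rows.append(
            {
                "depth_bin": b,
                "t": t,
                "dof": len(wide) - 1,
                "p_raw": p,
                "p_corrected": min(1.0, p * correction),
                "significant": min(1.0, p * correction) < 0.05,
            }
        )
    return pd.DataFrame(rows)


def build_preference_maps(
    weights: np.ndarray, labels: dict, tie_rtol: float = 1e-9
) -> PreferenceMap:
    """Argmax-weight acoustic preferences from modulation-model weights.

    ``weights`` is (128, n_points) in bin-major order; ``labels`` carries
    ``bin_centers`` (Hz), ``rates`` and ``scales``.  Best frequency is the
    bin maximising the weight marginal summed over (rate, scale); best
    rate/scale are argmaxes of their marginals.  Ties take the lowest
    labelled value and set the tie flag; all-zero weights are undefined.
    """
    centers = np.asarray(labels["bin_centers"], dtype=float)
    rates = np.asarray(labels["rates"], dtype=float)
    scales = np.asarray(labels["scales"], dtype=float)
    nb, nr, ns = len(centers), len(rates), len(scales)
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != nb * nr * ns:
        raise ValueError("weight rows do not match the bin-major label layout")
    n_points = w.shape[1]
    cube = w.reshape(nb, nr, ns, n_points)

    undefined = np.all(w == 0, axis=0)
    marg_b = cube.sum(axis=(1, 2))
    marg_r = cube.sum(axis=(0, 2))
    marg_s = cube.sum(axis=(0, 1))

    def _argmax_with_ties(marg):
        best = np.argmax(marg, axis=0)
        mx = marg.max(axis=0)
        tie = (np.isclose(marg, mx[None, :], rtol=tie_rtol, atol=0).sum(axis=0)) > 1
        return best, tie

    bi, tb = _argmax_with_ties(marg_b)
    ri, tr_ = _argmax_with_ties(marg_r)
    si, ts = _argmax_with_ties(marg_s)
    bf = centers[bi].astype(float)
    rate = rates[ri].astype(float)
    scale = scales[si].astype(float)
    for arr in (bf, rate, scale):
        arr[undefined] = np.nan
    return PreferenceMap(
        best_frequency_hz=bf,
        best_rate_hz=rate,
        best_scale_cpo=scale,
        tie_flags=(tb | tr_ | ts) & ~undefined,
        undefined=undefined,
    )


def map_correlation_test(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    min_units: int = 4,
) -> dict:
    """Across-unit test of the correlation between two preference maps.

    ``maps_a``/``maps_b`` are (units x grid points), NaN where undefined.
    Per unit the Pearson correlation over jointly finite points is Fisher
    (atanh) transformed; the transformed values enter a two-tailed
    Wilcoxon signed-rank test.  The group median maps keep points present
    in at least ``min_units`` units.  Degenerate inputs (all transformed
    values identical) are flagged rather than tested.
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("maps must be (units x points) with matching shapes")
    if a.shape[0] < 2:
        raise ValueError("need >= 2 units")
    rs = []
    for u in range(a.shape[0]):
        ok = np.isfinite(a[u]) & np.isfinite(b[u])
        if ok.sum() < 3:
            rs.append(np.nan)
            continue
        rs.append(float(stats.pearsonr(a[u, ok], b[u, ok]).statistic))
    rs = np.asarray(rs)
    valid = np.isfinite(rs)
    z = np.arctanh(np.clip(rs[valid], -1 + 1e-12, 1 - 1e-12))

    degenerate = z.size < 2 or np.allclose(z, z[0])
    if degenerate:
        stat, p = np.nan, np.nan
    else:
        w = stats.wilcoxon(z, alternative="two-sided")
        stat, p = float(w.statistic), float(w.pvalue)

    def _median_map(m):
        count = np.isfinite(m).sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(m, axis=0)
        med[count < min_units] = np.nan
        return med

    return {
        "per_unit_r": rs,
        "mean_r": float(np.nanmean(rs)) if valid.any() else np.nan,
        "sem_r": (
            float(np.nanstd(rs[valid], ddof=1) / np.sqrt(valid.sum()))
            if valid.sum() > 1
            else np.nan
        ),
        "statistic": stat,
        "p_value": p,
        "degenerate": bool(degenerate),
        "median_map_a": _median_map(a),
        "median_map_b": _median_map(b),
        "n_units": int(valid.sum()),
    }
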