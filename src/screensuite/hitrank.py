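"""Consensus ranking of virtual-screening hits.

Each hit carries two affinity estimates — a docking score (Glide gscore)
and an MM-GBSA binding free energy (ΔG_bind), both in kcal/mol with lower
meaning better. Five complementary ranking strategies are applied:

1. equal-weight z-score averaging,
2. percentile ranking (robust to outliers),
3. weighted z-score averaging (default 40 % docking / 60 % MM-GBSA),
4. Pareto non-dominated sorting with iterative frontier peeling,
5. strict dual-cutoff filtering (gscore <= -6.0 and ΔG <= -40.0 kcal/mol)
   followed by z-score ranking of the passers.

The ensemble rank is the arithmetic mean of the five per-method ranks.
Ties always receive average (fractional) ranks; rows missing either metric
are excluded before ranking and counted in the summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_score_table",
    "zscore_rank",
    "percentile_rank",
    "weighted_zscore_rank",
    "pareto_rank",
    "pareto_frontiers",
    "strict_cutoff_rank",
    "ensemble_rank",
    "score_summary",
    "RankingResult",
]

GSCORE = "gscore"
DGBIND = "dg_bind"


def load_score_table(
    path: str | Path,
    id_col: str = "compound_id",
    g_col: str = "gscore",
    dg_col: str = "dg_bind",
) -> tuple[pd.DataFrame, int]:
    """Read a score CSV; returns ``(table, n_missing_excluded)``.

    The returned table has canonical column names and unique compound ids;
    rows with a missing value in either metric are dropped and counted.
    """
    df = pd.read_csv(path)
    df = df.rename(columns={id_col: "compound_id", g_col: GSCORE, dg_col: DGBIND})
    for col in ("compound_id", GSCORE, DGBIND):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    if df["compound_id"].duplicated().any():
        raise ValueError("compound ids must be unique")
    n0 = len(df)
    df = df.dropna(subset=[GSCORE, DGBIND]).reset_index(drop=True)
    return df, n0 - len(df)


def _zcolumn(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        warnings.warn("zero variance column: z-scores set to 0")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _ascending_rank(combined: np.ndarray) -> np.ndarray:
    """Rank 1 = smallest combined value; ties get average ranks."""
    return stats.rankdata(combined, method="average")


def zscore_rank(table: pd.DataFrame) -> np.ndarray:
    """Equal-weight z-score rank: most negative mean z ranks first."""
    z = (_zcolumn(table[GSCORE].to_numpy()) + _zcolumn(table[DGBIND].to_numpy())) / 2
    return _ascending_rank(z)


def percentile_rank(table: pd.DataFrame) -> np.ndarray:
    """Percentile rank: per metric, most negative scores map near 100; the
    two percentiles are averaged and ranked descending."""
    n = len(table)
    pct_g = 100.0 * stats.rankdata(-table[GSCORE].to_numpy(), method="average") / n
    pct_dg = 100.0 * stats.rankdata(-table[DGBIND].to_numpy(), method="average") / n
    return _ascending_rank(-(pct_g + pct_dg) / 2)


def weighted_zscore_rank(
    table: pd.DataFrame, w_g: float = 0.4, w_dg: float = 0.6
) -> np.ndarray:
    """Weighted z-score rank; default weights favor MM-GBSA (0.6 vs 0.4)."""
    z = w_g * _zcolumn(table[GSCORE].to_numpy()) + w_dg * _zcolumn(
        table[DGBIND].to_numpy()
    )
    return _ascending_rank(z)


def _nondominated_mask(g: np.ndarray, dg: np.ndarray) -> np.ndarray:
    """Boolean mask of rows not dominated by any other (minimize both).

    Row a dominates b iff a <= b in both metrics and a < b in at least one;
    exact duplicates are mutually non-dominating.
    """
    n = g.size
    order = np.lexsort((dg, g))  # by g asc, then dg asc
    mask = np.zeros(n, dtype=bool)
    best_dg_strict = np.inf  # min dg among rows with strictly smaller g
    i = 0
    while i < n:
        j = i
        gi = g[order[i]]
        # group of equal g
        while j < n and g[order[j]] == gi:
            j += 1
        group = order[i:j]
        group_min_dg = dg[group].min()
        for idx in group:
            # survives iff minimal dg within its g-group and not beaten by a
            # strictly-smaller-g row with dg <= its dg
            if dg[idx] == group_min_dg and dg[idx] < best_dg_strict:
                mask[idx] = True
        best_dg_strict = min(best_dg_strict, group_min_dg)
        i = j
    return mask


def pareto_frontiers(table: pd.DataFrame) -> list[list[str]]:
    """Iteratively peel non-dominated frontiers; returns lists of compound
    ids, frontier 1 first."""
    g = table[GSCORE].to_numpy(dtype=float)
    dg = table[DGBIND].to_numpy(dtype=float)
    ids = table["compound_id"].to_numpy()
    remaining = np.ones(g.size, dtype=bool)
    fronts: list[list[str]] = []
    while remaining.any():
        idx = np.where(remaining)[0]
        mask = _nondominated_mask(g[idx], dg[idx])
        front = idx[mask]
        fronts.append(list(ids[front]))
        remaining[front] = False
    return fronts


def pareto_rank(table: pd.DataFrame) -> tuple[np.ndarray, list[list[str]]]:
    """Hierarchical Pareto ranks from frontier peeling.

    All members of frontier f share the same peel level; levels are then
    converted to average fractional ranks so that they are commensurable
    with the other methods.
    """
    fronts = pareto_frontiers(table)
    level_of = {cid: f for f, members in enumerate(fronts, start=1) for cid in members}
    levels = np.array([level_of[c] for c in table["compound_id"]], dtype=float)
    return _ascending_rank(levels), fronts


def strict_cutoff_rank(
    table: pd.DataFrame, g_cut: float = -6.0, dg_cut: float = -40.0
) -> tuple[np.ndarray, np.ndarray]:
    """Dual-cutoff rank: passers (gscore <= g_cut and ΔG <= dg_cut, both
    inclusive) are z-score-ranked among themselves; non-passers follow all
    passers, ordered by their own z-score combination.

    Returns ``(ranks, pass_mask)``.
    """
    g = table[GSCORE].to_numpy(dtype=float)
    dg = table[DGBIND].to_numpy(dtype=float)
    passes = (g <= g_cut) & (dg <= dg_cut)
    ranks = np.empty(len(table), dtype=float)
    n_pass = int(passes.sum())
    if n_pass:
        sub = table.loc[passes]
        ranks[passes] = zscore_rank(sub)
    if n_pass < len(table):
        sub = table.loc[~passes]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny non-passer sets may be constant
            ranks[~passes] = n_pass + zscore_rank(sub)
    return ranks, passes


@dataclass
class RankingResult:
    """Output of :func:`ensemble_rank`."""

    table: pd.DataFrame  # input columns + five rank columns + ensemble_rank
    pareto_front_ids: list[str]
    frontiers: list[list[str]]
    pass_mask: np.ndarray
    summary: dict


def ensemble_rank(
    table: pd.DataFrame,
    w_g: float = 0.4,
    w_dg: float = 0.6,
    g_cut: float = -6.0,
    dg_cut: float = -40.0,
    n_missing: int = 0,
) -> RankingResult:
    """Run all five methods and average their ranks into an ensemble rank."""
    df = table.reset_index(drop=True).copy()
    if df.empty:
        raise ValueError("empty score table")
    df["rank_zscore"] = zscore_rank(df)
    df["rank_percentile"] = percentile_rank(df)
    df["rank_weighted"] = weighted_zscore_rank(df, w_g=w_g, w_dg=w_dg)
    pranks, fronts = pareto_rank(df)
    df["rank_pareto"] = pranks
    cranks, passes = strict_cutoff_rank(df, g_cut=g_cut, dg_cut=dg_cut)
    df["rank_cutoff"] = cranks
    rank_cols = [
        "rank_zscore", "rank_percentile", "rank_weighted", "rank_pareto", "rank_cutoff"
    ]
    df["ensemble_rank"] = df[rank_cols].mean(axis=1)
    df["final_rank"] = _ascending_rank(df["ensemble_rank"].to_numpy())
    level_of = {cid: f for f, members in enumerate(fronts, start=1) for cid in members}
    df["pareto_frontier"] = [level_of[c] for c in df["compound_id"]]
    summary = score_summary(df, g_cut=g_cut, dg_cut=dg_cut)
    summary["n_missing_excluded"] = n_missing
    return RankingResult(
        table=df,
        pareto_front_ids=fronts[0],
        frontiers=fronts,
        pass_mask=passes,
        summary=summary,
    )


def score_summary(
    table: pd.DataFrame,
    g_cut: float = -6.0,
    dg_cut: float = -40.0,
    outdir: str | Path | None = None,
    top_n_highlight: int = 20,
) -> dict:
    """Distribution summary of the two metrics (+ optional plots).

    Reports per-metric mean/sd/median/min/max, their Pearson correlation,
    n, and the dual-cutoff pass count/fraction. A constant column makes the
    correlation undefined; it is reported as NaN with a warning.
    """
    g = table[GSCORE].to_numpy(dtype=float)
    dg = table[DGBIND].to_numpy(dtype=float)

    def _stats(x: np.ndarray) -> dict:
        return {
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
            "median": float(np.median(x)),
            "min": float(x.min()),
            "max": float(x.max()),
        }

    if g.std() == 0 or dg.std() == 0 or g.size < 2:
        warnings.warn("Pearson R undefined (constant column or n < 2)")
        r = float("nan")
    else:
        r = float(stats.pearsonr(g, dg).statistic)
    passes = (g <= g_cut) & (dg <= dg_cut)
    summary = {
        "n": int(len(table)),
        "gscore": _stats(g),
        "dg_bind": _stats(dg),
        "pearson_r": r,
        "cutoff_pass_count": int(passes.sum()),
        "cutoff_pass_fraction": float(passes.mean()) if len(table) else float("nan"),
    }
    if outdir is not None:
        plot_score_panels(table, summary, Path(outdir), top_n_highlight)
    return summary


def plot_score_panels(
    table: pd.DataFrame, summary: dict, outdir: Path, top_n_highlight: int = 20
) -> list[Path]:
    """Histogram pair, Pareto scatter with frontier overlay, box plots and
    correlation scatter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    g = table[GSCORE].to_numpy(dtype=float)
    dg = table[DGBIND].to_numpy(dtype=float)

    def _save(fig, name):
        p = outdir / name
        fig.savefig(p, dpi=100, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    for col, name, label in ((g, "A_gscore_hist.png", "Glide gscore (kcal/mol)"),
                             (dg, "B_dg_hist.png", "MM-GBSA ΔG_bind (kcal/mol)")):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.hist(col, bins=50)
        ax.axvline(np.median(col), color="red", linestyle="--",
                   label=f"median {np.median(col):.2f}")
        ax.set_xlabel(label); ax.set_ylabel("count"); ax.legend()
        _save(fig, name)

    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    if "pareto_frontier" in table:
        sc = ax.scatter(g, dg, c=table["pareto_frontier"], s=8, cmap="viridis")
        fig.colorbar(sc, label="Pareto frontier")
        front = table[table["pareto_frontier"] == 1].sort_values(GSCORE)
        ax.plot(front[GSCORE], front[DGBIND], "r--")
        ax.plot(front[GSCORE], front[DGBIND], "r*", markersize=12,
                label=f"frontier 1 (n={len(front)})")
        if "final_rank" in table:
            top = table.nsmallest(top_n_highlight, "final_rank")
            ax.scatter(top[GSCORE], top[DGBIND], facecolors="limegreen",
                       edgecolors="black", s=40, label=f"top {top_n_highlight} ensemble")
        ax.legend(fontsize=7)
    else:
        ax.scatter(g, dg, s=8)
    ax.set_xlabel("Glide gscore (kcal/mol)"); ax.set_ylabel("MM-GBSA ΔG_bind (kcal/mol)")
    _save(fig, "C_pareto_scatter.png")

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot([g, dg], tick_labels=["gscore", "ΔG_bind"], showmeans=True)
    ax.set_ylabel("kcal/mol")
    _save(fig, "D_boxplots.png")

    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(g, dg, s=6, alpha=0.4)
    ax.set_xlabel("Glide gscore"); ax.set_ylabel("ΔG_bind")
    ax.set_title(f"R = {summary['pearson_r']:.3f}, n = {summary['n']}")
    _save(fig, "E_correlation.png")
    return written
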