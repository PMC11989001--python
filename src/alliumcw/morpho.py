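"""Cell-size morphometry and the proportional-constant-growth model.

Epidermal cell areas are grouped by layer (S1..S6) and zone (basal,
middle, upper).  The proportional-constant-growth model (PCGM) states
that two zones of a layer share one size distribution up to a constant
multiplicative factor: cells in the basal and upper zones are scaled
replicas of the middle-zone cells.  The test rescales the source zone by
an estimated (or supplied) factor and compares the rescaled sample with
the target zone using a two-sample Kolmogorov-Smirnov test; failing to
reject supports proportional growth.

Also provides per-group summaries (median, quartiles, IQR) and generic
group comparisons (Kruskal-Wallis with Dunn's post hoc, or pairwise
Welch t-tests).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LAYER_VOCAB = ("S1", "S2", "S3", "S4", "S5", "S6")
ZONE_VOCAB = ("B", "M", "U")


def validate_cell_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a cell-size table (onion_id, layer, zone, area_um2)."""
    required = {"layer", "zone", "area_um2"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cell-size table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("cell-size table is empty")
    if not (table["area_um2"] > 0).all():
        raise ValueError("all areas must be strictly positive")
    bad_layers = set(table["layer"]) - set(LAYER_VOCAB)
    if bad_layers:
        raise ValueError(f"unknown layers: {sorted(bad_layers)}")
    bad_zones = set(table["zone"]) - set(ZONE_VOCAB)
    if bad_zones:
        raise ValueError(f"unknown zones: {sorted(bad_zones)}")
    return table


@dataclass(frozen=True)
class PCGMResult:
    """Outcome of one proportional-growth comparison between two zones."""

    layer: str
    from_zone: str
    to_zone: str
    factor: float
    ks_statistic: float
    p_value: float
    alpha: float
    reject: bool
    n_from: int
    n_to: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.ks_statistic <= 1.0
        assert 0.0 <= self.p_value <= 1.0
        assert self.reject == (self.p_value < self.alpha)


def summarize_sizes(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(layer, zone) n, median, quartiles and IQR.

    Quantiles use linear interpolation (numpy's default, the type-7
    convention) so the printed IQRs are bit-reproducible.  Empty groups
    are omitted with a warning.
    """
    validate_cell_table(table)
    rows = []
    for (layer, zone), grp in table.groupby(["layer", "zone"], sort=True):
        areas = grp["area_um2"].to_numpy()
        if areas.size == 0:  # pragma: no cover - groupby drops empties
            logger.warning("empty group (%s, %s) omitted", layer, zone)
            continue
        q1, med, q3 = np.percentile(areas, [25, 50, 75])
        rows.append(
            {
                "layer": layer,
                "zone": zone,
                "n": int(areas.size),
                "median": med,
                "q1": q1,
                "q3": q3,
                "iqr": q3 - q1,
            }
        )
    return pd.DataFrame(rows)


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sample p; degenerate-variance groups get an exact 0/1."""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def _dunn_pvalues(
    groups: dict[str, np.ndarray], adjust: str = "bonferroni"
) -> dict[tuple[str, str], float]:
    """Dunn's rank-based post hoc z-tests with tie correction."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    # mean rank per group
    mean_rank: dict[str, float] = {}
    start = 0
    for g in names:
        size = groups[g].size
        mean_rank[g] = float(ranks[start : start + size].mean())
        start += size
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(names, 2))
    out: dict[tuple[str, str], float] = {}
    for ga, gb in pairs:
        se = math.sqrt(base_var * (1.0 / groups[ga].size + 1.0 / groups[gb].size))
        z = (mean_rank[ga] - mean_rank[gb]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * len(pairs))
        out[(ga, gb)] = float(p)
    return out


def pairwise_tests(
    table: pd.DataFrame,
    value_col: str,
    group_col: str,
    method: str = "kruskal_dunn",
) -> dict:
    """Compare groups of a numeric column.

    ``kruskal_dunn`` runs the global Kruskal-Wallis test followed by
    Dunn's pairwise z-tests (Bonferroni-adjusted); ``unpaired_t`` runs a
    Welch two-sample t-test for every pair.  Returns
    ``{"global_p": float | None, "pairwise": {(a, b): p}}``.
    """
    groups = {
        str(name): grp[value_col].to_numpy(dtype=float)
        for name, grp in table.groupby(group_col, sort=True)
    }
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    if method == "kruskal_dunn":
        for name, vals in groups.items():
            if vals.size < 1:
                raise ValueError(f"group {name} is empty")
        global_p = float(stats.kruskal(*groups.values()).pvalue)
        return {"global_p": global_p, "pairwise": _dunn_pvalues(groups)}
    if method == "unpaired_t":
        for name, vals in groups.items():
            if vals.size < 2:
                raise ValueError(f"group {name} needs >= 2 observations for a t-test")
        pairwise = {
            (ga, gb): _welch_p(groups[ga], groups[gb])
            for ga, gb in itertools.combinations(groups, 2)
        }
        return {"global_p": None, "pairwise": pairwise}
    raise ValueError(f"unknown method {method!r}; use 'kruskal_dunn' or 'unpaired_t'")


def _zone_areas(
    table: pd.DataFrame, layer: str, zone: str, min_n: int
) -> np.ndarray:
    sel = table[(table["layer"] == layer) & (table["zone"] == zone)]
    areas = sel["area_um2"].to_numpy(dtype=float)
    if areas.size == 0:
        raise ValueError(f"no cells for layer {layer}, zone {zone}")
    if areas.size < min_n:
        raise ValueError(
            f"insufficient data for layer {layer}, zone {zone}: "
            f"{areas.size} cells < {min_n} required"
        )
    return areas


def estimate_growth_factor(
    table: pd.DataFrame, layer: str, from_zone: str, to_zone: str
) -> float:
    """Constant growth factor c = median(to zone) / median(from zone).

    The ratio of medians is robust against the heavy right tails of
    cell-area distributions, and medians compose: the B->M and M->U
    factors multiply exactly to the B->U factor.
    """
    validate_cell_table(table)
    a_from = _zone_areas(table, layer, from_zone, min_n=5)
    a_to = _zone_areas(table, layer, to_zone, min_n=5)
    return float(np.median(a_to) / np.median(a_from))


def pcgm_test(
    table: pd.DataFrame,
    layer: str,
    from_zone: str = "B",
    to_zone: str = "M",
    alpha: float = 0.05,
    factor: float | None = None,
) -> PCGMResult:
    """Test proportional constant growth between two zones of a layer.

    Multiplies every ``from_zone`` area by the growth factor (estimated
    from the medians unless supplied) and compares the rescaled sample
    with the ``to_zone`` sample using a two-sample two-sided
    Kolmogorov-Smirnov test (exact p for combined n < 50, asymptotic
    otherwise).  ``reject=False`` means the data are compatible with the
    two zones sharing one distribution up to a constant scale.

    The factor convention is always median(target)/median(source), so
    the shrinking direction (e.g. M -> U) simply runs the comparison the
    other way with a factor > 1; no negative factors are needed.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    validate_cell_table(table)
    a_from = _zone_areas(table, layer, from_zone, min_n=5)
    a_to = _zone_areas(table, layer, to_zone, min_n=5)
    c = factor if factor is not None else float(np.median(a_to) / np.median(a_from))
    if c <= 0:
        raise ValueError("growth factor must be > 0")
    method = "exact" if a_from.size + a_to.size < 50 else "asymp"
    res = stats.ks_2samp(a_from * c, a_to, method=method)
    p = float(res.pvalue)
    return PCGMResult(
        layer=layer,
        from_zone=from_zone,
        to_zone=to_zone,
        factor=float(c),
        ks_statistic=float(res.statistic),
        p_value=p,
        alpha=alpha,
        reject=bool(p < alpha),
        n_from=int(a_from.size),
        n_to=int(a_to.size),
    )


def pcgm_scan(
    table: pd.DataFrame, alpha: float = 0.05
) -> list[PCGMResult]:
    """Run the B->M and U->M comparisons for every layer present."""
    validate_cell_table(table)
    results = []
    for layer in sorted(table["layer"].unique()):
        zones = set(table.loc[table["layer"] == layer, "zone"])
        for from_zone in ("B", "U"):
            if from_zone in zones and "M" in zones:
                results.append(pcgm_test(table, layer, from_zone, "M", alpha=alpha))
    return results
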