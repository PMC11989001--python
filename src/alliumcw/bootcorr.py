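"""Bootstrap Pearson correlation between unpaired grouped samples.

Biochemical assays and gene-expression measurements are typically made
on *different* onions, so their values cannot be paired directly.  Both
modalities, however, share the three-layer structure (S1, S2, S6): each
physical sample contributes a *triple* of values, one per layer.  The
bootstrap repeatedly pairs a random biochemistry triple with a random
expression triple, matches values of the same layer, and computes a
Pearson correlation over the pooled layer-matched points; the replicate
distribution yields a mean r, a percentile confidence interval and a
sign-based p-value.

Triples are standardized within their onion (mean 0, sd 1 over the
three layers) before pairing, which removes between-onion level shifts
and makes the estimate invariant to which onions happen to be paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYER_ORDER = ("S1", "S2", "S6")


@dataclass(frozen=True)
class BootstrapResult:
    """Replicate summary of one (feature, gene) bootstrap correlation."""

    feature: str
    gene: str
    n_replicates: int
    r_mean: float
    ci_low: float
    ci_high: float
    p_value: float
    seed: int

    def __post_init__(self) -> None:
        assert -1.0 <= self.ci_low <= self.r_mean <= self.ci_high <= 1.0
        assert 0.0 <= self.p_value <= 1.0

    @property
    def strong_positive(self) -> bool:
        return self.r_mean > 0.8

    @property
    def strong_negative(self) -> bool:
        return self.r_mean < -0.8


def normalize_within_onion(triple: np.ndarray) -> np.ndarray:
    """Standardize one onion's layer triple to mean 0 and sample sd 1.

    Uses the sample (ddof=1) standard deviation.  A constant triple has
    no scale and raises ``ValueError``; pipeline callers exclude such
    triples with a warning instead of imputing them.
    """
    t = np.asarray(triple, dtype=float)
    if t.shape[-1] != 3:
        raise ValueError("a triple must have exactly three layer values")
    sd = t.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate triple: all three values are equal")
    return (t - t.mean()) / sd


def _normalize_set(values: np.ndarray, label: str, normalize: bool) -> np.ndarray:
    """Row-wise standardization of an (n, 3) triple array, dropping constants."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != 3:
        raise ValueError(f"{label}: expected an (n, 3) array of layer triples")
    keep = values.std(axis=1, ddof=1) > 0
    if not keep.all():
        logger.warning(
            "%s: excluded %d degenerate (constant) triple(s)", label, int((~keep).sum())
        )
    values = values[keep]
    if values.shape[0] == 0:
        raise ValueError(f"{label}: no usable triples after degenerate exclusion")
    if normalize:
        values = (values - values.mean(axis=1, keepdims=True)) / values.std(
            axis=1, ddof=1, keepdims=True
        )
    return values


def bootstrap_pair_correlation(
    biochem: np.ndarray,
    expression: np.ndarray,
    n_replicates: int = 2000,
    seed: int = 0,
    normalize_biochem: bool = True,
    feature: str = "",
    gene: str = "",
) -> BootstrapResult:
    """Bootstrap Pearson correlation between two unpaired triple sets.

    Per replicate, ``m = min(n_biochem, n_expression)`` pairs of triples
    are drawn with replacement from the two sets and their layer-matched
    values concatenated into ``3 m`` (x, y) points; Pearson r is computed
    on that pool.  After ``n_replicates`` draws the replicate
    distribution gives the mean r, the 2.5/97.5 percentile interval and
    a two-sided sign p-value ``2 * min(P(r* <= 0), P(r* >= 0))``.

    Expression triples are always standardized within their onion;
    biochemistry triples are standardized too unless
    ``normalize_biochem=False``.  Replicates where either axis is
    constant are dropped; if all replicates degenerate, ``ValueError``.
    """
    if n_replicates < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    bio = _normalize_set(biochem, "biochem", normalize=normalize_biochem)
    expr = _normalize_set(expression, "expression", normalize=True)
    m = min(bio.shape[0], expr.shape[0])
    rng = np.random.default_rng(seed)
    bi = rng.integers(0, bio.shape[0], size=(n_replicates, m))
    ei = rng.integers(0, expr.shape[0], size=(n_replicates, m))
    x = bio[bi].reshape(n_replicates, 3 * m)
    y = expr[ei].reshape(n_replicates, 3 * m)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    valid = (sx > 0) & (sy > 0)
    if not valid.any():
        raise ValueError("estimation failure: every bootstrap replicate was degenerate")
    r = (xc[valid] * yc[valid]).sum(axis=1) / (sx[valid] * sy[valid])
    r = np.clip(r, -1.0, 1.0)
    ci_low, ci_high = np.percentile(r, [2.5, 97.5])
    r_mean = float(r.mean())
    p = 2.0 * min(float(np.mean(r <= 0)), float(np.mean(r >= 0)))
    return BootstrapResult(
        feature=feature,
        gene=gene,
        n_replicates=int(valid.sum()),
        r_mean=r_mean,
        ci_low=float(min(ci_low, r_mean)),
        ci_high=float(max(ci_high, r_mean)),
        p_value=min(p, 1.0),
        seed=seed,
    )


def triples_from_long(
    table: pd.DataFrame,
    value_col: str,
    layers: tuple[str, str, str] = LAYER_ORDER,
) -> np.ndarray:
    """Pivot a long (onion_id, layer, value) frame into an (n, 3) array.

    Onions missing any of the three layers are dropped with a warning:
    the bootstrap requires complete triples.
    """
    wide = table.pivot_table(
        index="onion_id", columns="layer", values=value_col, aggfunc="mean"
    )
    missing_cols = [l for l in layers if l not in wide.columns]
    if missing_cols:
        raise ValueError(f"layers absent from table: {missing_cols}")
    wide = wide[list(layers)]
    complete = wide.dropna()
    if len(complete) < len(wide):
        logger.warning(
            "dropped %d onion(s) with incomplete layer triples",
            len(wide) - len(complete),
        )
    return complete.to_numpy(dtype=float)


def correlation_matrix(
    biochem: pd.DataFrame,
    expression: pd.DataFrame,
    features: list[str] | None = None,
    genes: list[str] | None = None,
    n_replicates: int = 2000,
    seed: int = 0,
    normalize_biochem: bool = True,
) -> list[BootstrapResult]:
    """Bootstrap correlation for every (gene, feature) pair.

    ``biochem`` is wide (onion_id, layer, one column per feature);
    ``expression`` is long (gene, onion_id, layer, value — the value
    column may be named ``value`` or ``ratio``).  Pairs are flagged
    strong when |r_mean| exceeds 0.8 strictly.  Each pair gets an
    independent child seed derived from ``seed``, so results do not
    depend on evaluation order.
    """
    if features is None:
        features = [
            c
            for c in biochem.columns
            if c not in ("onion_id", "layer", "sample_id")
            and pd.api.types.is_numeric_dtype(biochem[c])
        ]
    value_col = "value" if "value" in expression.columns else "ratio"
    if genes is None:
        genes = sorted(expression["gene"].unique())
    if not features or not genes:
        raise ValueError("need at least one feature and one gene")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(genes) * len(features))
    results = []
    k = 0
    for gene in genes:
        expr_triples = triples_from_long(
            expression[expression["gene"] == gene], value_col
        )
        for feat in features:
            bio_triples = triples_from_long(biochem, feat)
            child_seed = int(children[k].generate_state(1)[0] % 2**31)
            k += 1
            results.append(
                bootstrap_pair_correlation(
                    bio_triples,
                    expr_triples,
                    n_replicates=n_replicates,
                    seed=child_seed,
                    normalize_biochem=normalize_biochem,
                    feature=feat,
                    gene=gene,
                )
            )
    return results


def results_frame(results: list[BootstrapResult]) -> pd.DataFrame:
    """Long-format results table with CIs, p-values and strength flags."""
    return pd.DataFrame(
        {
            "gene": r.gene,
            "feature": r.feature,
            "r_mean": r.r_mean,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p_value": r.p_value,
            "n_replicates": r.n_replicates,
            "strong_positive": r.strong_positive,
            "strong_negative": r.strong_negative,
        }
        for r in results
    )


def matrix_frame(results: list[BootstrapResult]) -> pd.DataFrame:
    """Genes x features matrix of mean bootstrap correlations."""
    long = results_frame(results)
    return long.pivot(index="gene", columns="feature", values="r_mean")
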