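"""Efficiency-corrected relative qPCR quantification (Pfaffl method).

Expression of a target gene is reported relative to a calibrator
condition and normalized to a reference (housekeeping) gene measured in
the same sample:

    ratio = E_target ** dCq_target / E_ref ** dCq_ref

where ``E`` is the per-gene amplification efficiency (fold of product
per cycle, 2 for a perfect doubling) and ``dCq = Cq(calibrator) -
Cq(sample)``.  When both efficiencies are 2 this reduces to the
classical ``2**(-ddCq)`` method.  Efficiencies come from standard-curve
slopes via ``E = 10**(-1/slope)``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency from a standard-curve slope.

    ``slope`` is the fitted change in Cq per log10 dilution step; the
    canonical -3.3219 gives E = 2 (perfect doubling).  A usable assay
    has |slope| roughly in 3.1-3.6 (E between ~1.9 and ~2.1); this
    function does not enforce that band, it only converts.
    """
    if slope == 0:
        raise ZeroDivisionError("standard-curve slope must be non-zero")
    return 10.0 ** (-1.0 / slope)


def pfaffl_ratio(
    e_target: float, dcq_target: float, e_ref: float, dcq_ref: float
) -> float:
    """Relative expression ratio E_t**dCq_t / E_r**dCq_r.

    ``dcq_*`` are calibrator-minus-sample Cq differences, so a target
    that amplifies earlier (lower Cq) than in the calibrator yields a
    ratio above 1.
    """
    for name, e in (("target", e_target), ("reference", e_ref)):
        if not 1.0 < e <= 2.0:
            raise ValueError(f"{name} efficiency {e} must be in (1, 2]")
    return e_target**dcq_target / e_ref**dcq_ref


def relative_expression(
    qpcr: pd.DataFrame,
    efficiencies: dict[str, float] | None = None,
    reference_gene: str = "actin",
    calibrator_layer: str = "S1",
) -> pd.DataFrame:
    """Pfaffl relative expression per (gene, onion, layer).

    ``qpcr`` is long-format with columns ``gene``, ``onion_id``,
    ``layer``, ``cq``.  Replicate Cq values within a (gene, onion,
    layer) cell are arithmetically averaged first (a geometric mean on
    the concentration scale); each target gene's dCq against the
    calibrator layer is then corrected by the reference gene's dCq
    within the same onion.  Genes absent from ``efficiencies`` default
    to E = 2.

    Returns columns ``gene``, ``onion_id``, ``layer``, ``ratio``; the
    calibrator layer's own rows have ratio 1 by construction.
    """
    required = {"gene", "onion_id", "layer", "cq"}
    missing = required - set(qpcr.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    if (qpcr["cq"] <= 0).any():
        raise ValueError("all Cq values must be positive")
    efficiencies = efficiencies or {}

    mean_cq = (
        qpcr.groupby(["gene", "onion_id", "layer"], sort=True)["cq"]
        .mean()
        .rename("cq")
    )
    genes = sorted(qpcr["gene"].unique())
    if reference_gene not in genes:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")

    # completeness: reference gene and calibrator layer per onion
    gaps = []
    onions = sorted(qpcr["onion_id"].unique())
    layers = sorted(qpcr["layer"].unique())
    for onion in onions:
        for layer in layers:
            if (reference_gene, onion, layer) not in mean_cq.index:
                gaps.append((reference_gene, onion, layer))
        for gene in genes:
            if (gene, onion, calibrator_layer) not in mean_cq.index:
                gaps.append((gene, onion, calibrator_layer))
    if gaps:
        raise ValueError(f"missing reference/calibrator measurements: {sorted(set(gaps))}")

    e_ref = efficiencies.get(reference_gene, 2.0)
    rows = []
    for gene in genes:
        if gene == reference_gene:
            continue
        e_t = efficiencies.get(gene, 2.0)
        for onion in onions:
            cal_t = mean_cq[(gene, onion, calibrator_layer)]
            cal_r = mean_cq[(reference_gene, onion, calibrator_layer)]
            for layer in layers:
                if (gene, onion, layer) not in mean_cq.index:
                    continue
                dcq_t = cal_t - mean_cq[(gene, onion, layer)]
                dcq_r = cal_r - mean_cq[(reference_gene, onion, layer)]
                rows.append(
                    {
                        "gene": gene,
                        "onion_id": onion,
                        "layer": layer,
                        "ratio": pfaffl_ratio(e_t, dcq_t, e_ref, dcq_r),
                    }
                )
    return pd.DataFrame(rows)


def mean_expression(expression: pd.DataFrame) -> pd.DataFrame:
    """Geometric-mean ratio per (gene, layer) across onions.

    Ratios are log-symmetric, so the geometric mean is the natural
    across-onion summary.
    """
    out = (
        expression.assign(log_ratio=np.log(expression["ratio"]))
        .groupby(["gene", "layer"], sort=True)["log_ratio"]
        .mean()
        .pipe(np.exp)
        .rename("ratio")
        .reset_index()
    )
    return out
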