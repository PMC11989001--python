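"""Synthetic datasets with known ground truth for every analysis stage.

The generator emulates the statistical structure of an onion-epidermis
study without any wet-lab input:

* **Cell sizes** — per (layer, zone) lognormal area distributions.  The
  basal (B) and upper (U) zone distributions are the middle-zone (M)
  distribution scaled down by constant factors ``c_BM`` and ``c_UM``, so
  the proportional-constant-growth null holds exactly by construction.
* **FTIR spectra** — sums of Gaussian bands centred on the canonical
  cell-wall intervals with layer-dependent amplitudes, plus a smooth
  baseline and iid noise on an 800-1800 cm^-1 grid.
* **Biochemical features** — layer-ordered means with multiplicative
  (CV-based) replicate noise, appropriate for positive concentrations.
* **qPCR Cq values** — the exact inverse of the Pfaffl ratio model, so
  the configured true expression ratios are recovered exactly at zero
  Cq noise; the reference gene is flat across layers.

Defaults follow reported middle-zone medians for layers S1-S6 and
reported alpha-cellulose contents; everything else (dispersions, factor
sizes, noise levels) is a documented free choice.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from alliumcw import ftir

LAYERS = ("S1", "S2", "S3", "S4", "S5", "S6")
ZONES = ("B", "M", "U")

#: Middle-zone median cell areas (um^2) for layers S1..S6.
DEFAULT_M_MEDIANS: dict[str, float] = {
    "S1": 26750.2,
    "S2": 17932.3,
    "S3": 17547.0,
    "S4": 8636.9,
    "S5": 6511.7,
    "S6": 1540.1,
}

#: Reported alpha-cellulose content (ug/mg dry cell wall) per layer,
#: plus plausible layer-ordered means for the other standard assays.
DEFAULT_BIOCHEM_MEANS: dict[tuple[str, str], float] = {
    ("S1", "alpha_cellulose"): 495.9,
    ("S2", "alpha_cellulose"): 431.2,
    ("S6", "alpha_cellulose"): 349.2,
    ("S1", "total_sugars"): 620.0,
    ("S2", "total_sugars"): 560.0,
    ("S6", "total_sugars"): 430.0,
    ("S1", "uronic_acids"): 180.0,
    ("S2", "uronic_acids"): 205.0,
    ("S6", "uronic_acids"): 240.0,
    ("S1", "reducing_sugars"): 55.0,
    ("S2", "reducing_sugars"): 70.0,
    ("S6", "reducing_sugars"): 110.0,
}


def _default_zone_factors() -> dict[str, tuple[float, float]]:
    # (c_BM, c_UM): multiplicative expansion from B to M and U to M.
    return {layer: (2.0, 1.5) for layer in LAYERS}


def _default_peak_spec() -> list[dict]:
    """One Gaussian band per canonical interval, amplitudes ordered S1>S2>S6.

    Cellulose/glucan-type bands decay towards the youngest layer, while
    the pectin-ester and aromatic bands increase, mirroring the usual
    maturation trend of epidermal cell walls.
    """
    increasing = {"Int6", "Int10", "Int11"}
    peaks = []
    for iv in ftir.canonical_intervals():
        width = iv.width / 6.0
        if iv.name in increasing:
            amps = {"S1": 0.6, "S2": 0.8, "S6": 1.0}
        else:
            amps = {"S1": 1.0, "S2": 0.8, "S6": 0.6}
        peaks.append(
            {
                "center": iv.midpoint,
                "width": width,
                "amplitude": amps,
            }
        )
    return peaks


def _default_qpcr_truth() -> dict[tuple[str, str], float]:
    # Fold change vs the calibrator layer S1 for three cell-wall-enzyme
    # genes; values span up- and down-regulation at realistic magnitude.
    return {
        ("PME", "S1"): 1.0,
        ("PME", "S2"): 2.0,
        ("PME", "S6"): 8.0,
        ("XTH", "S1"): 1.0,
        ("XTH", "S2"): 1.5,
        ("XTH", "S6"): 4.0,
        ("PG", "S1"): 1.0,
        ("PG", "S2"): 0.7,
        ("PG", "S6"): 0.25,
    }


@dataclass
class SynthConfig:
    """Parameters of the synthetic world.

    Counts must be positive; amplification efficiencies live in (1, 2]
    (fold-per-cycle); noise levels are non-negative.  ``zone_factors``
    maps each layer to ``(c_BM, c_UM)``, both > 1, meaning cells expand
    from the basal and upper zones towards the middle zone.
    """

    seed: int = 0
    n_onions: int = 9
    cells_per_zone: int = 150
    layer_zone_medians: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_M_MEDIANS)
    )
    lognormal_sigma: float = 0.6
    zone_factors: dict[str, tuple[float, float]] = field(
        default_factory=_default_zone_factors
    )
    spectrum_grid: tuple[float, float, float] = (800.0, 1800.0, 2.0)
    peak_spec: list[dict] = field(default_factory=_default_peak_spec)
    baseline_drift: float = 0.05
    noise_sd: float = 0.01
    spectra_per_layer: int = 6
    biochem_means: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BIOCHEM_MEANS)
    )
    biochem_cv: float = 0.08
    qpcr_truth: dict[tuple[str, str], float] = field(
        default_factory=_default_qpcr_truth
    )
    efficiency: dict[str, float] = field(
        default_factory=lambda: {"actin": 2.0, "PME": 2.0, "XTH": 2.0, "PG": 2.0}
    )
    reference_gene: str = "actin"
    calibrator_layer: str = "S1"
    cq_noise_sd: float = 0.15

    def validate(self) -> None:
        def bad(name: str, why: str) -> ValueError:
            return ValueError(f"invalid SynthConfig.{name}: {why}")

        if self.n_onions <= 0:
            raise bad("n_onions", "must be > 0")
        if self.cells_per_zone <= 0:
            raise bad("cells_per_zone", "must be > 0")
        if self.spectra_per_layer <= 0:
            raise bad("spectra_per_layer", "must be > 0")
        lo, hi, step = self.spectrum_grid
        if step <= 0:
            raise bad("spectrum_grid", "step must be > 0")
        if not lo < hi:
            raise bad("spectrum_grid", "lo must be < hi")
        if self.lognormal_sigma < 0:
            raise bad("lognormal_sigma", "must be >= 0")
        if self.noise_sd < 0 or self.cq_noise_sd < 0 or self.biochem_cv < 0:
            raise bad("noise", "noise levels must be >= 0")
        if self.baseline_drift < 0:
            raise bad("baseline_drift", "must be >= 0")
        for layer, med in self.layer_zone_medians.items():
            if med <= 0:
                raise bad("layer_zone_medians", f"median for {layer} must be > 0")
        for layer, (c_bm, c_um) in self.zone_factors.items():
            if c_bm <= 1 or c_um <= 1:
                raise bad(
                    "zone_factors",
                    f"{layer}: c_BM and c_UM must be > 1 (cells expand towards M)",
                )
        for peak in self.peak_spec:
            if not lo <= peak["center"] <= hi:
                raise bad(
                    "peak_spec",
                    f"peak center {peak['center']} outside grid [{lo}, {hi}]",
                )
            if peak["width"] <= 0:
                raise bad("peak_spec", "peak width must be > 0")
        for gene, e in self.efficiency.items():
            if not 1.0 < e <= 2.0:
                raise bad("efficiency", f"{gene}: E={e} must be in (1, 2]")
        for (gene, layer), ratio in self.qpcr_truth.items():
            if ratio <= 0:
                raise bad("qpcr_truth", f"({gene}, {layer}): ratio must be > 0")

    def grid(self) -> np.ndarray:
        lo, hi, step = self.spectrum_grid
        return np.arange(lo, hi + step / 2, step)


def _rng(config: SynthConfig, stream: str) -> np.random.Generator:
    # Independent, reproducible stream per generator; crc32 is stable
    # across processes (builtin hash() is salted).
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(zlib.crc32(stream.encode()),))
    )


def gen_cell_sizes(config: SynthConfig) -> pd.DataFrame:
    """Sample per-cell areas for each onion, layer and zone.

    For every layer the middle-zone areas are lognormal with the
    configured median and shape ``lognormal_sigma``; basal and upper
    areas are drawn from the same distribution scaled by ``1/c_BM`` and
    ``1/c_UM``.  Because a lognormal is closed under multiplicative
    scaling, the rescaled B (or U) distribution equals the M
    distribution exactly, so the constant-growth null is true by
    construction.

    Returns a long DataFrame with columns ``onion_id``, ``layer``,
    ``zone``, ``area_um2``.
    """
    config.validate()
    rng = _rng(config, "cells")
    rows: list[pd.DataFrame] = []
    for onion in range(1, config.n_onions + 1):
        for layer, m_median in config.layer_zone_medians.items():
            c_bm, c_um = config.zone_factors.get(layer, (2.0, 1.5))
            for zone, factor in (("B", c_bm), ("M", 1.0), ("U", c_um)):
                mu = math.log(m_median / factor)
                areas = rng.lognormal(
                    mean=mu, sigma=config.lognormal_sigma, size=config.cells_per_zone
                )
                rows.append(
                    pd.DataFrame(
                        {
                            "onion_id": f"O{onion}",
                            "layer": layer,
                            "zone": zone,
                            "area_um2": areas,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def _gaussian(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def gen_spectra(config: SynthConfig) -> list[ftir.Spectrum]:
    """Simulate replicate FTIR spectra per layer.

    Each spectrum is a sum of Gaussian bands (one per entry of
    ``peak_spec``, amplitude chosen by the spectrum's layer), a smooth
    baseline (linear drift plus a half-period cosine of amplitude
    ``baseline_drift``) and iid Gaussian noise of sd ``noise_sd``.
    """
    config.validate()
    rng = _rng(config, "spectra")
    grid = config.grid()
    lo, hi, _ = config.spectrum_grid
    layers = sorted({l for peak in config.peak_spec for l in peak["amplitude"]})
    spectra: list[ftir.Spectrum] = []
    for layer in layers:
        for rep in range(1, config.spectra_per_layer + 1):
            signal = np.zeros_like(grid)
            for peak in config.peak_spec:
                amp = peak["amplitude"].get(layer, 0.0)
                signal += amp * _gaussian(grid, peak["center"], peak["width"])
            if config.baseline_drift > 0:
                slope = rng.uniform(-1, 1) * config.baseline_drift
                bow = rng.uniform(0, 1) * config.baseline_drift
                t = (grid - lo) / (hi - lo)
                signal = signal + slope * t + bow * 0.5 * (1 - np.cos(np.pi * t))
            if config.noise_sd > 0:
                signal = signal + rng.normal(0.0, config.noise_sd, size=grid.size)
            spectra.append(
                ftir.Spectrum(
                    wavenumbers=grid,
                    absorbance=signal,
                    sample_id=f"{layer}_r{rep}",
                    layer=layer,
                )
            )
    return spectra


def gen_biochem(config: SynthConfig) -> pd.DataFrame:
    """Simulate a biochemical feature table with layer-ordered means.

    One replicate per onion and layer; each value is
    ``mean * (1 + Normal(0, cv))``, i.e. multiplicative noise with the
    configured coefficient of variation, as befits positive
    concentration measurements.
    """
    config.validate()
    rng = _rng(config, "biochem")
    layers = sorted({layer for layer, _ in config.biochem_means})
    features = sorted({feat for _, feat in config.biochem_means})
    for layer in layers:
        for feat in features:
            if (layer, feat) not in config.biochem_means:
                raise ValueError(
                    f"invalid SynthConfig.biochem_means: missing mean for "
                    f"({layer}, {feat})"
                )
    rows = []
    for onion in range(1, config.n_onions + 1):
        for layer in layers:
            row: dict[str, object] = {"sample_id": f"O{onion}_{layer}",
                                      "onion_id": f"O{onion}", "layer": layer}
            for feat in features:
                mean = config.biochem_means[(layer, feat)]
                row[feat] = mean * (1.0 + rng.normal(0.0, config.biochem_cv))
            rows.append(row)
    return pd.DataFrame(rows)


def gen_qpcr(config: SynthConfig) -> pd.DataFrame:
    """Simulate a Cq table whose Pfaffl ratios equal ``qpcr_truth``.

    The reference gene is held at a constant Cq across layers, so its
    calibrator-minus-sample difference is zero.  For a target gene with
    efficiency ``E`` and true ratio ``r`` in a layer, the generated Cq is
    ``Cq_cal - log(r)/log(E)``: plugging these into the Pfaffl formula
    recovers ``r`` exactly when ``cq_noise_sd`` is zero.  Gaussian cycle
    noise is then added to every Cq.

    Returns a long DataFrame with columns ``gene``, ``onion_id``,
    ``layer``, ``cq``.
    """
    config.validate()
    rng = _rng(config, "qpcr")
    genes = sorted({gene for gene, _ in config.qpcr_truth})
    layers = sorted({layer for _, layer in config.qpcr_truth})
    if config.calibrator_layer not in layers:
        raise ValueError(
            "invalid SynthConfig.qpcr_truth: no entry for the calibrator layer "
            f"{config.calibrator_layer!r}"
        )
    base_cq = {gene: 24.0 + 2.0 * i for i, gene in enumerate(genes)}
    ref_cq = 20.0
    rows = []
    for onion in range(1, config.n_onions + 1):
        for layer in layers:
            rows.append(
                {
                    "gene": config.reference_gene,
                    "onion_id": f"O{onion}",
                    "layer": layer,
                    "cq": ref_cq + rng.normal(0.0, config.cq_noise_sd),
                }
            )
            for gene in genes:
                try:
                    ratio = config.qpcr_truth[(gene, layer)]
                except KeyError:
                    raise ValueError(
                        f"invalid SynthConfig.qpcr_truth: missing ratio for "
                        f"({gene}, {layer})"
                    ) from None
                e_t = config.efficiency.get(gene, 2.0)
                cq = base_cq[gene] - math.log(ratio) / math.log(e_t)
                rows.append(
                    {
                        "gene": gene,
                        "onion_id": f"O{onion}",
                        "layer": layer,
                        "cq": cq + rng.normal(0.0, config.cq_noise_sd),
                    }
                )
    return pd.DataFrame(rows)


def gen_correlated_triples(
    n_biochem: int,
    n_expression: int,
    population_r: float,
    seed: int,
    layer_means: tuple[float, float, float] = (-1.0, 0.0, 1.0),
    noise_sd: float = 0.432,
) -> tuple[np.ndarray, np.ndarray]:
    """Unpaired biochemistry/expression triples with a controlled link.

    Both sides share layer-level means over (S1, S2, S6); the expression
    means are ``population_r``-signed copies of the biochemistry means
    when ``|population_r| > 0`` and unrelated (flat) when it is 0.
    Per-triple Gaussian noise of sd ``noise_sd`` is added independently.
    Returns two arrays of shape ``(n, 3)``.

    The association between the two sides runs entirely through the
    shared layer means, so the population correlation of layer-matched,
    within-onion-normalized values is set by the means/noise ratio; the
    default ``noise_sd`` of 0.432 is calibrated (numerically, once) so
    that ratio yields a population r of +/-0.90 for the default means,
    and a flat expression profile yields exactly 0.
    """
    rng = np.random.default_rng(seed)
    means = np.asarray(layer_means, dtype=float)
    bio = means + rng.normal(0.0, noise_sd, size=(n_biochem, 3))
    if population_r == 0:
        expr = rng.normal(0.0, 1.0, size=(n_expression, 3))
    else:
        expr_means = math.copysign(1.0, population_r) * means
        expr = expr_means + rng.normal(0.0, noise_sd, size=(n_expression, 3))
    return bio, expr
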