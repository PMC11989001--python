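"""CSV readers/writers for the pipeline's tabular interchange formats.

Formats:

* cell sizes — long CSV: ``onion_id, layer, zone, area_um2``
* spectra — wide CSV: first column ``wavenumber``, one column per
  sample; layer labels in a sidecar CSV ``sample_id, layer``
* features — CSV: ``sample_id, layer`` plus one numeric column per feature
* qPCR — long CSV: ``gene, onion_id, layer, cq``; efficiencies in an
  optional CSV with ``gene`` and either ``E`` or ``slope``
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from alliumcw import ftir, qpcr


def read_cells(path: str | Path) -> pd.DataFrame:
    from alliumcw import morpho

    return morpho.validate_cell_table(pd.read_csv(path))


def write_cells(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_spectra(
    spectra: list[ftir.Spectrum], path: str | Path, labels_path: str | Path
) -> None:
    wide = {"wavenumber": spectra[0].wavenumbers}
    labels = []
    for s in spectra:
        wide[s.sample_id] = s.absorbance
        labels.append({"sample_id": s.sample_id, "layer": s.layer})
    pd.DataFrame(wide).to_csv(path, index=False)
    pd.DataFrame(labels).to_csv(labels_path, index=False)


def read_spectra(
    path: str | Path, labels_path: str | Path | None = None
) -> list[ftir.Spectrum]:
    wide = pd.read_csv(path)
    if "wavenumber" not in wide.columns:
        raise ValueError("spectra CSV must have a 'wavenumber' first column")
    layer_of: dict[str, str] = {}
    if labels_path is not None:
        lab = pd.read_csv(labels_path)
        layer_of = dict(zip(lab["sample_id"].astype(str), lab["layer"].astype(str)))
    w = wide["wavenumber"].to_numpy(dtype=float)
    return [
        ftir.Spectrum(
            wavenumbers=w,
            absorbance=wide[col].to_numpy(dtype=float),
            sample_id=str(col),
            layer=layer_of.get(str(col)),
        )
        for col in wide.columns
        if col != "wavenumber"
    ]


def read_features(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "layer" not in table.columns:
        raise ValueError("feature CSV must have a 'layer' column")
    return table


def write_features(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_qpcr(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = {"gene", "onion_id", "layer", "cq"} - set(table.columns)
    if missing:
        raise ValueError(f"qPCR CSV missing columns: {sorted(missing)}")
    return table


def read_efficiencies(path: str | Path) -> dict[str, float]:
    """Per-gene efficiencies from a CSV with an ``E`` or ``slope`` column."""
    table = pd.read_csv(path)
    if "E" in table.columns:
        return dict(zip(table["gene"], table["E"].astype(float)))
    if "slope" in table.columns:
        return {
            g: qpcr.efficiency_from_slope(s)
            for g, s in zip(table["gene"], table["slope"].astype(float))
        }
    raise ValueError("efficiency CSV needs an 'E' or 'slope' column")
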