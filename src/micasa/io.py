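"""Reading condition image sets and writing tabular results.

Two input conventions are supported, mirroring common two-marker imaging
workflows: RGB images whose red and green planes hold the two markers
(any blue counterstain plane is ignored), or pairs of single-channel
grayscale images matched by a shared base name plus per-channel
identifier tokens.  TIFF (8/16-bit) and PNG are accepted.  Images are
converted to floating point; no intensity normalization is applied beyond
the per-image mean subtraction performed in the spectral stage, so
log-spectra are offset by overall gain but confidence intervals compare
like with like.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .core import AnalysisConfig, ConditionDataset, ImageChannel
from .radial import RadialGrid
from .stats import CURVE_NAMES, CIFunction, ComparisonReport, MiCASAResult

__all__ = [
    "load_condition",
    "write_radial_csv",
    "save_result",
    "load_result",
    "write_comparison",
]

IMAGE_SUFFIXES = (".tif", ".tiff", ".png")
DEFAULT_CHANNEL_TOKENS = ("_ch1", "_ch2")


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    return np.asarray(iio.imread(path))


def _image_files(directory: Path) -> list[Path]:
    files = [
        p
        for p in sorted(directory.iterdir())
        if p.suffix.lower() in IMAGE_SUFFIXES and p.is_file()
    ]
    if not files:
        raise FileNotFoundError(
            f"no TIFF/PNG images found in {directory}"
        )
    return files


def load_condition(
    directory: str | Path,
    mode: str,
    pixel_size_um: float,
    channel_tokens: Sequence[str] = DEFAULT_CHANNEL_TOKENS,
    label: str | None = None,
) -> ConditionDataset:
    """Load one condition's image pairs from a directory.

    ``mode="rgb"``: every image must carry >= 3 colour planes; channel A
    is the red plane, channel B the green plane.  ``mode="paired"``:
    grayscale files are grouped by base name after stripping one of the
    two ``channel_tokens``; unmatched files are an error.  Pair order
    follows sorted filename order.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"{directory} is not a directory")
    files = _image_files(directory)
    pairs: list[tuple[ImageChannel, ImageChannel]] = []

    if mode == "rgb":
        for path in files:
            arr = _read_image(path)
            if arr.ndim != 3 or arr.shape[-1] < 3:
                raise ValueError(
                    f"{path.name}: rgb mode needs images with >= 3 colour "
                    f"planes, got shape {arr.shape}"
                )
            red = arr[..., 0].astype(float)
            green = arr[..., 1].astype(float)
            pairs.append(
                (ImageChannel(red, pixel_size_um), ImageChannel(green, pixel_size_um))
            )
    elif mode == "paired":
        tok_a, tok_b = channel_tokens
        groups: dict[str, dict[str, Path]] = {}
        orphans: list[str] = []
        for path in files:
            stem = path.stem
            if tok_a in stem:
                groups.setdefault(stem.replace(tok_a, "", 1), {})["a"] = path
            elif tok_b in stem:
                groups.setdefault(stem.replace(tok_b, "", 1), {})["b"] = path
            else:
                orphans.append(path.name)
        incomplete = [k for k, v in groups.items() if len(v) != 2]
        if orphans or incomplete:
            missing = orphans + [
                f"{k} (only {next(iter(groups[k].values())).name})" for k in incomplete
            ]
            raise ValueError(
                "paired mode: files without a partner "
                f"(tokens {tok_a!r}/{tok_b!r}): " + ", ".join(sorted(missing))
            )
        for key in sorted(groups):
            arr_a = _read_image(groups[key]["a"]).astype(float)
            arr_b = _read_image(groups[key]["b"]).astype(float)
            if arr_a.ndim != 2 or arr_b.ndim != 2:
                raise ValueError(f"pair {key!r}: paired mode expects grayscale images")
            if arr_a.shape != arr_b.shape:
                raise ValueError(
                    f"pair {key!r}: channel shapes differ "
                    f"({arr_a.shape} vs {arr_b.shape})"
                )
            pairs.append(
                (
                    ImageChannel(arr_a, pixel_size_um),
                    ImageChannel(arr_b, pixel_size_um),
                )
            )
    else:
        raise ValueError(f"mode must be 'rgb' or 'paired', got {mode!r}")

    return ConditionDataset(label=label or directory.name, pairs=tuple(pairs))


# ---------------------------------------------------------------------------
# results on disk: one CSV per curve plus a JSON manifest


def _curve_frame(ci: CIFunction) -> pd.DataFrame:
    grid = ci.grid
    est = np.where(ci.mask, np.nan, ci.estimate)
    lo = np.where(ci.mask, np.nan, ci.ci_lower)
    hi = np.where(ci.mask, np.nan, ci.ci_upper)
    return pd.DataFrame(
        {
            "frequency_cyc_per_um": grid.frequencies,
            "length_scale_um": grid.length_scales_um,
            "estimate": est,
            "ci_lower": lo,
            "ci_upper": hi,
        }
    )


def write_radial_csv(result: MiCASAResult, directory: str | Path) -> list[Path]:
    """Write one CSV per output curve (masked bins as empty fields)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in CURVE_NAMES:
        path = directory / f"{name}.csv"
        _curve_frame(result.curve(name)).to_csv(path, index=False)
        written.append(path)
    return written


def save_result(result: MiCASAResult, directory: str | Path) -> Path:
    """Persist a full result: per-curve CSVs plus a JSON run manifest."""
    directory = Path(directory)
    write_radial_csv(result, directory)
    manifest = {
        "software": "micasa",
        "version": __version__,
        "label": result.label,
        "N": result.N,
        "M": result.M,
        "NM": result.NM,
        "config": {
            "bandwidth_product": result.config.bandwidth_product,
            "n_tapers": result.config.n_tapers,
            "confidence_level": result.config.confidence_level,
            "radial_grid_size": result.config.radial_grid_size,
            "pixel_size_um": result.config.pixel_size_um,
        },
        "grid_bin_edges_cyc_per_um": list(result.grid.bin_edges),
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_result(directory: str | Path) -> MiCASAResult:
    """Reload a result written by :func:`save_result`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    grid = RadialGrid(
        frequencies=np.sqrt(
            np.asarray(manifest["grid_bin_edges_cyc_per_um"][:-1])
            * np.asarray(manifest["grid_bin_edges_cyc_per_um"][1:])
        ),
        bin_edges=np.asarray(manifest["grid_bin_edges_cyc_per_um"]),
    )
    cfg = AnalysisConfig(**manifest["config"])
    curves = {}
    for name in CURVE_NAMES:
        df = pd.read_csv(directory / f"{name}.csv")
        mask = df["estimate"].isna().to_numpy()
        curves[name] = CIFunction(
            grid=grid,
            estimate=np.nan_to_num(df["estimate"].to_numpy()),
            ci_lower=np.nan_to_num(df["ci_lower"].to_numpy()),
            ci_upper=np.nan_to_num(df["ci_upper"].to_numpy()),
            mask=mask,
            confidence_level=cfg.confidence_level,
            dof=manifest["NM"],
        )
    return MiCASAResult(
        config=cfg,
        label=manifest["label"],
        N=manifest["N"],
        M=manifest["M"],
        **curves,
    )


def write_comparison(report: ComparisonReport, directory: str | Path) -> Path:
    """Serialize a comparison as CSV (band list) and readable text."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for curve, bands in report.bands.items():
        for b in bands:
            rows.append(
                {
                    "curve": curve,
                    "direction_higher": b.direction,
                    "bin_start": b.bin_start,
                    "bin_stop": b.bin_stop,
                    "freq_lo_cyc_per_um": b.freq_lo,
                    "freq_hi_cyc_per_um": b.freq_hi,
                    "scale_hi_um": b.scale_hi_um,
                    "scale_lo_um": b.scale_lo_um,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "curve",
            "direction_higher",
            "bin_start",
            "bin_stop",
            "freq_lo_cyc_per_um",
            "freq_hi_cyc_per_um",
            "scale_hi_um",
            "scale_lo_um",
        ],
    ).to_csv(directory / "significant_bands.csv", index=False)
    text_path = directory / "comparison.txt"
    text_path.write_text(report.to_text() + "\n")
    return text_path
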