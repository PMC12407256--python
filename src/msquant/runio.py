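"""Run-directory serialization.

A run directory contains::

    manifest.json              seed + full config (loads are refused without a seed)
    windows/sNNNN_analyte.tsv  two-column (m/z, intensity) delimited text
    windows/sNNNN_is.tsv
    labels.json                truth labels, concentrations, true ratios

Quantification tables are delimited text; calibration curves are JSON.
Round-trips are lossless to float precision (values are written with repr
precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import LabeledDataset
from .windows import GRID_SPACING, WINDOW_LENGTH

_CHANNELS = ("analyte", "is")

#: Columns of a quantification table.
RESULT_COLUMNS = (
    "sample", "drug", "analyte_area", "is_area", "ratio", "conc", "bias_percent"
)


class RunFormatError(ValueError):
    """A run directory or one of its files is malformed."""


def _window_path(root: Path, sample: int, channel: str) -> Path:
    return root / "windows" / f"s{sample:04d}_{channel}.tsv"


def write_window_file(path: Path, grid: np.ndarray, intensities: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("mz\tintensity\n")
        for m, i in zip(grid, intensities):
            # %.17g round-trips IEEE doubles exactly
            fh.write(f"{m:.17g}\t{i:.17g}\n")


def read_window_file(path: Path) -> tuple[np.ndarray, np.ndarray]:
    mz, intensity = [], []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "mz\tintensity":
            raise RunFormatError(f"{path}: line 1: expected 'mz\\tintensity' header")
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if len(parts) != 2:
                raise RunFormatError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                mz.append(float(parts[0]))
                intensity.append(float(parts[1]))
            except ValueError as exc:
                raise RunFormatError(f"{path}: line {lineno}: {exc}") from None
    return np.array(mz), np.array(intensity)


def write_run(dataset: LabeledDataset, path, config: dict | None = None) -> Path:
    """Serialize a labeled dataset to a run directory."""
    root = Path(path)
    (root / "windows").mkdir(parents=True, exist_ok=True)
    manifest = {"seed": int(dataset.seed), "n_samples": int(dataset.n_samples),
                "config": config or {}}
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    samples = []
    for s in range(dataset.n_samples):
        entry = {
            "concentration": float(dataset.concentrations[s]),
            "true_ratio": float(dataset.true_ratios[s]),
        }
        for ch, name in enumerate(_CHANNELS):
            grid = GRID_SPACING * np.arange(WINDOW_LENGTH)
            write_window_file(
                _window_path(root, s, name), grid, dataset.windows[s, ch]
            )
            entry[f"label_{name}"] = dataset.labels[s, ch].astype(int).tolist()
        samples.append(entry)
    (root / "labels.json").write_text(json.dumps({"samples": samples}))
    return root


def read_run(path) -> tuple[LabeledDataset, dict]:
    """Load a run directory; refuses manifests without a recorded seed."""
    root = Path(path)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise RunFormatError(f"{root}: missing manifest.json")
    manifest = json.loads(manifest_path.read_text())
    if "seed" not in manifest:
        raise RunFormatError(f"{manifest_path}: manifest records no seed; refusing load")
    sidecar = json.loads((root / "labels.json").read_text())["samples"]
    n = len(sidecar)
    windows = np.zeros((n, 2, WINDOW_LENGTH))
    labels = np.zeros((n, 2, WINDOW_LENGTH), dtype=np.int8)
    concs = np.zeros(n)
    ratios = np.zeros(n)
    for s, entry in enumerate(sidecar):
        concs[s] = entry["concentration"]
        ratios[s] = entry["true_ratio"]
        for ch, name in enumerate(_CHANNELS):
            _, intensities = read_window_file(_window_path(root, s, name))
            if intensities.size != WINDOW_LENGTH:
                raise RunFormatError(
                    f"{_window_path(root, s, name)}: expected {WINDOW_LENGTH} points, "
                    f"got {intensities.size}"
                )
            windows[s, ch] = intensities
            labels[s, ch] = np.asarray(entry[f"label_{name}"], dtype=np.int8)
    return (
        LabeledDataset(windows=windows, labels=labels, concentrations=concs,
                       true_ratios=ratios, seed=int(manifest["seed"])),
        manifest,
    )


def write_results(path, records) -> Path:
    """Write a quantification table (list of dicts or DataFrame) as TSV."""
    df = pd.DataFrame(list(records), columns=list(RESULT_COLUMNS))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


def read_results(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise RunFormatError(f"{path}: {exc}") from None
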