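"""Plain-text point-file I/O, benchmark-case directories and run reports.

Point files hold one point per row, whitespace- or comma-separated, with
optional ``#`` comment lines.  Correspondence TSVs use 0-based indices
(noted in their headers).  Reports are JSON and, together with the recorded
seeds, reproduce a run exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .synthetic import BenchmarkCase, DegradationSpec

__all__ = [
    "read_points",
    "write_points",
    "read_truth_pairs",
    "write_truth_pairs",
    "write_case_dir",
    "read_case_dir",
    "write_report",
    "load_config",
]


class PointFileError(ValueError):
    """Malformed point file (ragged rows, non-numeric tokens, empty)."""


def read_points(path: str | Path) -> np.ndarray:
    """Read a whitespace/CSV point file; dimension inferred from columns."""
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            tokens = text.replace(",", " ").split()
            try:
                row = [float(t) for t in tokens]
            except ValueError as exc:
                raise PointFileError(f"{path}:{lineno}: non-numeric token ({exc})") from None
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise PointFileError(
                    f"{path}:{lineno}: expected {width} columns, found {len(row)}"
                )
            rows.append(row)
    if not rows:
        raise PointFileError(f"{path}: no point rows found")
    return np.asarray(rows, dtype=float)


def write_points(points: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(points, dtype=float), fmt="%.12g")


def write_truth_pairs(pairs, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# scene_idx\tmodel_idx (0-based)\n")
        for s, m in pairs:
            fh.write(f"{int(s)}\t{int(m)}\n")


def read_truth_pairs(path: str | Path) -> list[tuple[int, int]]:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if len(parts) < 2:
                raise PointFileError(f"{path}:{lineno}: expected two integer columns")
            pairs.append((int(parts[0]), int(parts[1])))
    return pairs


def write_case_dir(case: BenchmarkCase, directory: str | Path) -> Path:
    """Emit scene.txt, model.txt, truth.tsv and spec.json for one case."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_points(case.scene, directory / "scene.txt")
    write_points(case.model, directory / "model.txt")
    write_truth_pairs(case.truth_pairs, directory / "truth.tsv")
    if case.spec is not None:
        (directory / "spec.json").write_text(json.dumps(asdict(case.spec), indent=2))
    return directory


def read_case_dir(directory: str | Path) -> BenchmarkCase:
    directory = Path(directory)
    spec = None
    spec_path = directory / "spec.json"
    if spec_path.exists():
        spec = DegradationSpec(**json.loads(spec_path.read_text()))
    return BenchmarkCase(
        scene=read_points(directory / "scene.txt"),
        model=read_points(directory / "model.txt"),
        truth_pairs=read_truth_pairs(directory / "truth.tsv"),
        spec=spec,
    )


def write_report(report: dict, path: str | Path) -> None:
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default))


def load_config(path: str | Path) -> dict:
    """Key-value YAML config mirroring the CLI flags."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise PointFileError(f"{path}: config must be a mapping")
    return data
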