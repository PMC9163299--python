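"""Reading and writing sampled nerve-rootlet traces and experiment epoch plans.

This is the package's only I/O boundary.  Two on-disk trace formats are
supported:

* delimited text — one sample per line, with optional ``# key=value`` header
  lines (``rate_hz`` at minimum, optionally ``slice_id``);
* raw binary — little-endian 32-bit floats in ``<name>.f32`` with a JSON
  sidecar ``<name>.json`` holding ``rate_hz``, ``slice_id`` and free-form
  metadata.

Epoch plans (labelled drug-exposure intervals with an analysis window) are
stored as JSON arrays.  All times are in seconds with t=0 at the first sample
and half-open ``[start_s, end_s)`` intervals, so every burst belongs to at
most one epoch.

The loader rejects missing values rather than imputing them: artifact
handling is the job of :mod:`prebotpy.conditioning`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Sequence

import numpy as np

__all__ = [
    "Recording",
    "Epoch",
    "EpochPlan",
    "default_epoch_plan",
    "load_recording",
    "write_recording",
    "load_epoch_plan",
    "write_epoch_plan",
]


@dataclass
class Recording:
    """A uniformly sampled single-channel voltage trace.

    Parameters
    ----------
    samples:
        Sample values in arbitrary voltage units (AC-coupled extracellular
        signal; absolute scale carries no meaning and downstream analysis
        normalizes it away).
    rate_hz:
        Sampling rate in samples per second; must be positive.
    slice_id:
        Identifier of the slice preparation the trace came from.
    meta:
        Free-form provenance metadata (strain, age, condition notes).
    """

    samples: np.ndarray
    rate_hz: float
    slice_id: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size == 0:
            raise ValueError("samples must be non-empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if not (np.isfinite(self.rate_hz) and self.rate_hz > 0):
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz!r}")
        self.rate_hz = float(self.rate_hz)

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        """Time axis in seconds, t=0 at the first sample."""
        return np.arange(self.samples.size) / self.rate_hz

    def copy_with(self, samples: np.ndarray, rate_hz: float | None = None) -> "Recording":
        return Recording(
            samples=np.asarray(samples, dtype=np.float64),
            rate_hz=self.rate_hz if rate_hz is None else rate_hz,
            slice_id=self.slice_id,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class Epoch:
    """One labelled drug-condition interval ``[start_s, end_s)``.

    ``analysis_start_s`` marks where the analysed window begins (drug epochs
    are given time to stabilize; only their tail is summarized).
    """

    label: str
    start_s: float
    end_s: float
    analysis_start_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"epoch {self.label!r}: start_s must be < end_s")
        if not (self.start_s <= self.analysis_start_s < self.end_s):
            raise ValueError(
                f"epoch {self.label!r}: analysis_start_s must lie in [start_s, end_s)"
            )

    @property
    def analysis_window(self) -> tuple[float, float]:
        return (self.analysis_start_s, self.end_s)


@dataclass(frozen=True)
class EpochPlan:
    """Ordered, non-overlapping epochs with exactly one epoch labelled 'baseline'."""

    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        epochs = tuple(self.epochs)
        object.__setattr__(self, "epochs", epochs)
        if not epochs:
            raise ValueError("epoch plan must contain at least one epoch")
        for prev, cur in zip(epochs, epochs[1:]):
            if cur.start_s < prev.end_s:
                raise ValueError(
                    f"epochs {prev.label!r} and {cur.label!r} overlap or are unordered"
                )
        n_baseline = sum(1 for e in epochs if e.label == "baseline")
        if n_baseline != 1:
            raise ValueError(f"expected exactly one 'baseline' epoch, got {n_baseline}")

    def __iter__(self) -> Iterator[Epoch]:
        return iter(self.epochs)

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def baseline(self) -> Epoch:
        return next(e for e in self.epochs if e.label == "baseline")

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.epochs]

    def epoch_of(self, t_s: float) -> Epoch | None:
        """Epoch whose *analysis window* contains time ``t_s``, if any."""
        for e in self.epochs:
            if e.analysis_start_s <= t_s < e.end_s:
                return e
        return None


def default_epoch_plan(
    labels: Sequence[str],
    baseline_min: float = 10.0,
    drug_min: float = 20.0,
    analyzed_min: float = 10.0,
) -> EpochPlan:
    """Standard exposure protocol: a baseline analysed in full, then one
    epoch per drug condition with only its final ``analyzed_min`` minutes
    entering the analysis (the rhythm is allowed to stabilize first).

    With the defaults, the baseline spans ``[0, 600)`` s and each drug epoch
    is 1200 s long with the last 600 s analysed.
    """
    if not labels:
        raise ValueError("labels must be non-empty")
    if analyzed_min > drug_min:
        raise ValueError(
            f"analyzed_min ({analyzed_min}) must not exceed drug_min ({drug_min})"
        )
    if min(baseline_min, drug_min, analyzed_min) <= 0:
        raise ValueError("epoch durations must be positive")
    b_end = baseline_min * 60.0
    epochs = [Epoch("baseline", 0.0, b_end, 0.0)]
    t = b_end
    for label in labels:
        end = t + drug_min * 60.0
        epochs.append(Epoch(str(label), t, end, end - analyzed_min * 60.0))
        t = end
    return EpochPlan(tuple(epochs))


# ---------------------------------------------------------------------------
# Trace I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    return "binary" if path.suffix == ".f32" else "delimited"


def load_recording(
    path: str | Path,
    format: str | None = None,
    rate_hz: float | None = None,
    slice_id: str | None = None,
) -> Recording:
    """Load a trace from disk.

    ``format`` is inferred from the suffix when omitted (``.f32`` → binary).
    For delimited files the rate must come from a ``# rate_hz=`` header line
    or the ``rate_hz`` argument; a missing rate is a hard error, as are
    non-numeric or NaN rows (reported with their 1-based row number).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "binary":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing JSON sidecar for binary trace: {sidecar}")
        meta = json.loads(sidecar.read_text())
        if "rate_hz" not in meta:
            raise ValueError(f"sidecar {sidecar} lacks required key 'rate_hz'")
        samples = np.fromfile(path, dtype="<f4").astype(np.float64)
        return Recording(
            samples=samples,
            rate_hz=float(meta["rate_hz"]),
            slice_id=str(meta.get("slice_id", "")),
            meta=dict(meta.get("meta", {})),
        )
    if fmt != "delimited":
        raise ValueError(f"unknown trace format {fmt!r}")

    header: dict[str, str] = {}
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    header[key.strip()] = val.strip()
                continue
            try:
                v = float(line)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric sample at row {lineno}: {line!r}"
                ) from None
            if not np.isfinite(v):
                raise ValueError(f"{path}: missing/non-finite sample at row {lineno}")
            values.append(v)
    rate = rate_hz if rate_hz is not None else (
        float(header["rate_hz"]) if "rate_hz" in header else None
    )
    if rate is None:
        raise ValueError(f"{path}: no sampling rate (no '# rate_hz=' header and none given)")
    sid = slice_id if slice_id is not None else header.get("slice_id", "")
    meta = {k: v for k, v in header.items() if k not in ("rate_hz", "slice_id")}
    return Recording(np.asarray(values), rate, sid, meta)


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    """Write a trace to disk; returns the path written.

    The binary format stores 32-bit floats, so round-trips are bit-exact only
    for float32-representable samples; the delimited format prints full
    double precision.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "binary":
        rec.samples.astype("<f4").tofile(path)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {"rate_hz": rec.rate_hz, "slice_id": rec.slice_id, "meta": rec.meta},
                indent=2,
            )
        )
        return path
    if fmt != "delimited":
        raise ValueError(f"unknown trace format {fmt!r}")
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={rec.rate_hz!r}\n")
        if rec.slice_id:
            fh.write(f"# slice_id={rec.slice_id}\n")
        for k, v in rec.meta.items():
            fh.write(f"# {k}={v}\n")
        for v in rec.samples:
            fh.write(f"{float(v)!r}\n")
    return path


# ---------------------------------------------------------------------------
# Epoch-plan I/O
# ---------------------------------------------------------------------------

def write_epoch_plan(plan: EpochPlan, path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {
            "label": e.label,
            "start_s": e.start_s,
            "end_s": e.end_s,
            "analysis_start_s": e.analysis_start_s,
        }
        for e in plan
    ]
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_epoch_plan(path: str | Path) -> EpochPlan:
    payload = json.loads(Path(path).read_text())
    return EpochPlan(
        tuple(
            Epoch(d["label"], float(d["start_s"]), float(d["end_s"]), float(d["analysis_start_s"]))
            for d in payload
        )
    )
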