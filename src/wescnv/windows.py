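"""Reading, validation, normalization and encoding of exon-window depth matrices.

An exon-centered window is a fixed-length read-depth profile: 1002 consecutive
genomic bins covering an exon and its flanks, plus the window's genomic start
and end coordinate and its chromosome. Each window carries at most one CNV
label: 0 = no-call, 1 = deletion, 2 = duplication.

On disk a cohort matrix is delimited text with one window per row: 1002 depth
tokens in columns 0-1001, start and end in columns 1002-1003, the chromosome
identifier in column 1004, and an optional trailing label column. Padded or
missing depth bins are encoded as -1 and stay -1 through normalization so the
model can distinguish them from observed coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SEQ_LEN = 1002
MASK_TOKEN = -1.0

#: chromosome vocabulary, in one-hot index order (chr1..chr22, chrX, chrY)
CHROMOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")
_CHROM_INDEX = {c: i for i, c in enumerate(CHROMOSOMES)}

#: canonical class coding
CLASS_NAMES = ("NO-CALL", "DEL", "DUP")
_LABEL_ALIASES = {
    "NO-CALL": 0, "NOCALL": 0, "NO_CALL": 0, "0": 0,
    "DEL": 1, "DELETION": 1, "1": 1,
    "DUP": 2, "DUPLICATION": 2, "2": 2,
}


class FormatError(ValueError):
    """Malformed matrix row (wrong column count, unparsable field)."""


class VocabularyError(ValueError):
    """Chromosome name outside the chr1-22/X/Y vocabulary (e.g. chrMT)."""


class DegenerateInputError(ValueError):
    """Input carries no usable information (e.g. every depth token masked)."""


def canonical_chromosome(name: str) -> str:
    """Normalize a chromosome identifier to the canonical ``chrN`` form.

    Accepts ``chr1``/``1``/``X``/``chrX`` style names; rejects MT and anything
    else outside the 24-name vocabulary.
    """
    s = str(name).strip()
    if not s.lower().startswith("chr"):
        s = "chr" + s
    s = "chr" + s[3:].upper() if s[3:] in ("x", "y") else s
    if s not in _CHROM_INDEX:
        raise VocabularyError(
            f"chromosome {name!r} not in vocabulary chr1-chr22, chrX, chrY (MT excluded)"
        )
    return s


def parse_label(token) -> int:
    s = str(token).strip().upper()
    if s.endswith(".0"):
        s = s[:-2]
    if s not in _LABEL_ALIASES:
        raise FormatError(f"unrecognized class label {token!r}")
    return _LABEL_ALIASES[s]


@dataclass
class ExonWindow:
    """One exon-centered window: raw depth tokens plus genomic location.

    ``depths`` holds 1002 raw coverage values; -1 marks padded/missing bins.
    ``label`` is 0 (no-call), 1 (deletion), 2 (duplication) or None.
    """

    depths: np.ndarray
    start: int
    end: int
    chrom: str
    label: int | None = None
    sample_id: str = ""

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=np.float32)
        if self.depths.shape != (SEQ_LEN,):
            raise FormatError(
                f"expected {SEQ_LEN} depth tokens, got {self.depths.shape}"
            )
        bad = (self.depths < 0) & (self.depths != MASK_TOKEN)
        if bad.any():
            raise ValueError(
                f"negative depth tokens other than the -1 mask sentinel: "
                f"{self.depths[bad][:3]}..."
            )
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if self.start < 0:
            raise ValueError(f"negative start coordinate {self.start}")
        self.chrom = canonical_chromosome(self.chrom)
        if self.label is not None and self.label not in (0, 1, 2):
            raise ValueError(f"label must be 0/1/2, got {self.label}")

    @property
    def mask(self) -> np.ndarray:
        """Boolean vector, True at observed (non-padded) positions."""
        return self.depths != MASK_TOKEN

    @property
    def locus(self) -> tuple[str, int, int]:
        return (self.chrom, int(self.start), int(self.end))


@dataclass
class DepthScaler:
    """Min-max normalizer for depth tokens and genomic coordinates.

    Depth extrema are fitted over non-masked tokens only; start and end
    extrema are fitted independently over all windows. A degenerate range
    (max == min) maps every value to 0.
    """

    depth_min: float
    depth_max: float
    start_min: float
    start_max: float
    end_min: float
    end_max: float

    def _scale(self, x, lo: float, hi: float):
        if hi <= lo:
            return np.zeros_like(np.asarray(x, dtype=np.float32))
        return np.clip((np.asarray(x, dtype=np.float32) - lo) / (hi - lo), 0.0, 1.0)

    def scale_depth(self, d: np.ndarray) -> np.ndarray:
        return self._scale(d, self.depth_min, self.depth_max)

    def scale_start(self, s) -> np.ndarray:
        return self._scale(s, self.start_min, self.start_max)

    def scale_end(self, e) -> np.ndarray:
        return self._scale(e, self.end_min, self.end_max)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "DepthScaler":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class WindowTensor:
    """Model-ready encoding of a single window.

    ``channels``: (1002, 3) — normalized depth (or -1 at masked bins) and the
    normalized start/end coordinates broadcast along the sequence.
    ``chrom_onehot``: 24-dim indicator. ``mask``: True at observed bins.
    """

    channels: np.ndarray
    chrom_onehot: np.ndarray
    mask: np.ndarray = field(repr=False, default=None)


def encode_chromosome(chrom: str) -> np.ndarray:
    """One-hot encode a chromosome name into 24 dimensions (chr1-22, X, Y)."""
    v = np.zeros(len(CHROMOSOMES), dtype=np.float32)
    v[_CHROM_INDEX[canonical_chromosome(chrom)]] = 1.0
    return v


def fit_depth_scaler(windows: Iterable[ExonWindow]) -> DepthScaler:
    """Fit min-max extrema on a window collection (mask tokens excluded).

    Fit this on the training partition only and reuse the fitted scaler for
    validation, test and fine-tuning data to avoid leakage.
    """
    d_lo = np.inf
    d_hi = -np.inf
    s_lo = e_lo = np.inf
    s_hi = e_hi = -np.inf
    seen = False
    for w in windows:
        obs = w.depths[w.mask]
        if obs.size:
            seen = True
            d_lo = min(d_lo, float(obs.min()))
            d_hi = max(d_hi, float(obs.max()))
        s_lo, s_hi = min(s_lo, w.start), max(s_hi, w.start)
        e_lo, e_hi = min(e_lo, w.end), max(e_hi, w.end)
    if not seen:
        raise DegenerateInputError("every depth token is masked; cannot fit scaler")
    return DepthScaler(d_lo, d_hi, s_lo, s_hi, e_lo, e_hi)


def normalize_window(window: ExonWindow, scaler: DepthScaler) -> WindowTensor:
    """Encode one window into a (1002, 3) channel tensor + chromosome one-hot.

    Observed depths are min-max scaled (clamped to [0, 1] for out-of-range
    inputs); masked bins keep the -1 sentinel. Channels 1-2 are the
    normalized start/end repeated at every position.
    """
    mask = window.mask
    ch = np.empty((SEQ_LEN, 3), dtype=np.float32)
    ch[:, 0] = np.where(mask, scaler.scale_depth(window.depths), MASK_TOKEN)
    ch[:, 1] = scaler.scale_start(window.start)
    ch[:, 2] = scaler.scale_end(window.end)
    return WindowTensor(channels=ch, chrom_onehot=encode_chromosome(window.chrom), mask=mask)


def encode_batch(
    windows: Sequence[ExonWindow], scaler: DepthScaler
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`normalize_window` over a window collection.

    Returns ``(channels, chrom)`` with shapes (n, 1002, 3) and (n, 24).
    """
    n = len(windows)
    depths = np.stack([w.depths for w in windows])
    mask = depths != MASK_TOKEN
    ch = np.empty((n, SEQ_LEN, 3), dtype=np.float32)
    ch[:, :, 0] = np.where(mask, scaler.scale_depth(depths), MASK_TOKEN)
    ch[:, :, 1] = scaler.scale_start([w.start for w in windows])[:, None]
    ch[:, :, 2] = scaler.scale_end([w.end for w in windows])[:, None]
    chrom = np.stack([encode_chromosome(w.chrom) for w in windows])
    return ch, chrom


def labels_of(windows: Sequence[ExonWindow]) -> np.ndarray:
    lab = [w.label for w in windows]
    if any(l is None for l in lab):
        raise ValueError("unlabeled window in a labeled-only context")
    return np.asarray(lab, dtype=np.int64)


# ---------------------------------------------------------------------------
# matrix I/O


def read_window_matrix(
    path: str | Path,
    *,
    has_labels: bool | None = None,
    sample_id: str = "",
    delimiter: str | None = None,
) -> list[ExonWindow]:
    """Read a delimited exon-window matrix into :class:`ExonWindow` records.

    Each row must have 1005 columns (depths, start, end, chromosome) plus an
    optional label column; ``has_labels=None`` infers the dialect from the
    column count. ``delimiter=None`` splits on any whitespace.
    """
    path = Path(path)
    windows: list[ExonWindow] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter else line.split()
            ncol = len(parts)
            if has_labels is None:
                labelled = ncol == SEQ_LEN + 4
            else:
                labelled = has_labels
            expect = SEQ_LEN + 3 + (1 if labelled else 0)
            if ncol != expect:
                raise FormatError(
                    f"{path.name} row {i}: expected {expect} columns, found {ncol}"
                )
            try:
                depths = np.array(parts[:SEQ_LEN], dtype=np.float32)
                start = int(float(parts[SEQ_LEN]))
                end = int(float(parts[SEQ_LEN + 1]))
            except ValueError as exc:
                raise FormatError(f"{path.name} row {i}: {exc}") from exc
            label = parse_label(parts[SEQ_LEN + 3]) if labelled else None
            windows.append(
                ExonWindow(depths, start, end, parts[SEQ_LEN + 2], label, sample_id)
            )
    return windows


def write_window_matrix(windows: Sequence[ExonWindow], path: str | Path) -> None:
    """Write windows in the matrix dialect (tab-separated, label appended when present)."""
    with open(path, "w") as fh:
        for w in windows:
            cols = [np.format_float_positional(d, trim="-") for d in w.depths]
            cols += [str(int(w.start)), str(int(w.end)), w.chrom]
            if w.label is not None:
                cols.append(str(int(w.label)))
            fh.write("\t".join(cols) + "\n")


PREDICTION_COLUMNS = (
    "chrom", "start", "end", "sample_id", "p_nocall", "p_del", "p_dup", "call"
)


def write_predictions(
    windows: Sequence[ExonWindow],
    probabilities: np.ndarray,
    path: str | Path,
    *,
    bed_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write per-window class probabilities and hard calls as a TSV table.

    The hard call is the argmax class; exact probability ties resolve to the
    lowest class index (no-call < DEL < DUP). With ``bed_path``, DEL/DUP calls
    are additionally exported as BED intervals (name = class, score = 1000*p).
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    if probabilities.shape != (len(windows), 3):
        raise ValueError(
            f"probability array {probabilities.shape} does not match "
            f"{len(windows)} windows"
        )
    if len(windows) and not np.allclose(probabilities.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability triples must sum to 1")
    calls = probabilities.argmax(axis=1) if len(windows) else np.array([], dtype=int)
    df = pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [int(w.start) for w in windows],
            "end": [int(w.end) for w in windows],
            "sample_id": [w.sample_id for w in windows],
            "p_nocall": probabilities[:, 0] if len(windows) else [],
            "p_del": probabilities[:, 1] if len(windows) else [],
            "p_dup": probabilities[:, 2] if len(windows) else [],
            "call": [CLASS_NAMES[c] for c in calls],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for w, c, p in zip(windows, calls, probabilities):
                if c == 0:
                    continue
                if w.end <= w.start:
                    raise ValueError(f"BED interval requires end > start at {w.locus}")
                score = int(round(1000 * p[c]))
                fh.write(
                    f"{w.chrom}\t{int(w.start)}\t{int(w.end)}\t"
                    f"{CLASS_NAMES[c]}\t{score}\n"
                )
    return df


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"prediction table missing columns {sorted(missing)}")
    return df
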