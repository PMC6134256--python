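"""Shapiro–Senapathy-style consensus value (CV) scoring on a 0–100 scale.

Each matrix position holds the base frequencies observed in aligned splice
sites. A window's consensus value rescales the sum of observed-base
frequencies between the worst and best achievable windows:

    CV = 100 * (sum_i f_i(obs_i) - sum_i min_b f_i(b))
             / (sum_i max_b f_i(b) - sum_i min_b f_i(b))

so the per-position argmax sequence scores exactly 100 and the argmin
sequence exactly 0. The "SSF-like" and "HSF-style" scorers in this package
are both consensus-value scorers; they differ only in which matrix set and
which % score-variation threshold they are configured with.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

import numpy as np

__all__ = [
    "PWMatrix",
    "MatrixLibrary",
    "MatrixSchemaError",
    "load_matrix",
    "consensus_value",
    "scan_best_site",
    "default_library",
    "PSEUDO_FREQUENCY",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
PSEUDO_FREQUENCY = 1e-4  # added to every entry before renormalization


class MatrixSchemaError(ValueError):
    """Raised for malformed or inconsistent matrix files."""


def encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.intp, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-ACGT base {exc.args[0]!r} in sequence") from exc


@dataclass(frozen=True)
class PWMatrix:
    """A per-position base-frequency matrix over a boundary-anchored window.

    ``window_spec`` lists the signed offsets covered (contiguous, no 0) and
    ``freqs`` has one row per offset in A,C,G,T order. ``core_positions``
    are the offsets expected to carry the core dinucleotide; a scan can
    require them to match the matrix consensus.
    """

    name: str
    site_kind: str
    window_spec: tuple[int, ...]
    freqs: np.ndarray
    core_positions: tuple[int, ...] = ()

    def __post_init__(self):
        if self.site_kind not in ("donor", "acceptor"):
            raise MatrixSchemaError(f"{self.name}: bad site_kind {self.site_kind!r}")
        spec = tuple(self.window_spec)
        expected = tuple(o for o in range(spec[0], spec[-1] + 1) if o != 0)
        if spec != expected or 0 in spec:
            raise MatrixSchemaError(f"{self.name}: window offsets must be contiguous without 0")
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.shape != (len(spec), 4):
            raise MatrixSchemaError(f"{self.name}: frequency table shape {freqs.shape} != ({len(spec)}, 4)")
        if (freqs < 0).any():
            raise MatrixSchemaError(f"{self.name}: negative frequency")
        sums = freqs.sum(axis=1)
        if not np.all(np.abs(sums - 1) < 0.05):
            bad = int(np.argmax(np.abs(sums - 1)))
            raise MatrixSchemaError(
                f"{self.name}: frequencies at offset {spec[bad]} sum to {sums[bad]:.4f}, not ~1"
            )
        smoothed = freqs + PSEUDO_FREQUENCY
        smoothed /= smoothed.sum(axis=1, keepdims=True)
        smoothed.setflags(write=False)
        object.__setattr__(self, "freqs", smoothed)
        object.__setattr__(self, "window_spec", spec)
        core = tuple(self.core_positions)
        if not set(core) <= set(spec):
            raise MatrixSchemaError(f"{self.name}: core positions {core} outside window")
        object.__setattr__(self, "core_positions", core)

    def __len__(self) -> int:
        return len(self.window_spec)

    @property
    def consensus(self) -> str:
        """Per-position argmax sequence (ties broken toward A<C<G<T)."""
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))

    @property
    def anti_consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmin(axis=1))

    def offset_index(self, offset: int) -> int:
        return self.window_spec.index(offset)


def consensus_value(window: str, m: PWMatrix) -> float:
    """Consensus value of one window in [0, 100]."""
    if len(window) != len(m):
        raise ValueError(f"window length {len(window)} != matrix window {len(m)}")
    idx = encode(window)
    obs = m.freqs[np.arange(len(m)), idx].sum()
    lo = m.freqs.min(axis=1).sum()
    hi = m.freqs.max(axis=1).sum()
    return float(100.0 * (obs - lo) / (hi - lo))


def scan_best_site(
    seq: str,
    m: PWMatrix,
    floor: float = 0.0,
    require_core: bool = False,
) -> list[tuple[int, float]]:
    """Score every window of ``seq``; keep those with CV >= floor.

    When ``require_core`` is set, only windows whose core positions carry the
    matrix consensus bases (e.g. GT for a GT-donor matrix, GC for the GC
    variant) are reported. Results are sorted by score descending, ties by
    position ascending.
    """
    L = len(m)
    if len(seq) < L:
        return []
    idx = encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    scores = m.freqs[np.arange(L), windows].sum(axis=1)
    lo = m.freqs.min(axis=1).sum()
    hi = m.freqs.max(axis=1).sum()
    cvs = 100.0 * (scores - lo) / (hi - lo)
    keep = cvs >= floor
    if require_core and m.core_positions:
        cols = [m.offset_index(o) for o in m.core_positions]
        consensus_idx = m.freqs.argmax(axis=1)
        for c in cols:
            keep &= windows[:, c] == consensus_idx[c]
    hits = [(int(p), float(cvs[p])) for p in np.flatnonzero(keep)]
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits


# ---------------------------------------------------------------------------
# matrix files


def load_matrix(path) -> PWMatrix:
    """Load a matrix from TSV (``#name=/#site_kind=/#core=`` metadata lines,
    header ``offset A C G T``) or from an equivalent JSON document."""
    text = _read_text(path)
    if text.lstrip().startswith("{"):
        return _matrix_from_json(text, str(path))
    return _matrix_from_tsv(text, str(path))


def _read_text(path) -> str:
    with open(path) as fh:
        return fh.read()


def _matrix_from_json(text: str, label: str) -> PWMatrix:
    try:
        doc = json.loads(text)
        return PWMatrix(
            name=doc["name"],
            site_kind=doc["site_kind"],
            window_spec=tuple(doc["window_spec"]),
            freqs=np.array([[row[b] for b in BASES] for row in doc["freqs"]], dtype=float),
            core_positions=tuple(doc.get("core", [])),
        )
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise MatrixSchemaError(f"{label}: malformed JSON matrix ({exc})") from exc


def _matrix_from_tsv(text: str, label: str) -> PWMatrix:
    meta: dict[str, str] = {}
    offsets: list[int] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
            continue
        fields = line.split("\t")
        if fields[0] == "offset":
            if fields[1:5] != list(BASES):
                raise MatrixSchemaError(f"{label}:{lineno}: header must be 'offset A C G T'")
            continue
        if len(fields) != 5:
            raise MatrixSchemaError(f"{label}:{lineno}: expected 5 columns, got {len(fields)}")
        try:
            offsets.append(int(fields[0]))
            rows.append([float(x) for x in fields[1:5]])
        except ValueError as exc:
            raise MatrixSchemaError(f"{label}:{lineno}: malformed row ({exc})") from exc
    if not rows:
        raise MatrixSchemaError(f"{label}: no frequency rows")
    for key in ("name", "site_kind"):
        if key not in meta:
            raise MatrixSchemaError(f"{label}: missing '#{key}=' metadata line")
    order = np.argsort(offsets)
    core = tuple(int(x) for x in meta.get("core", "").split(",") if x.strip())
    return PWMatrix(
        name=meta["name"],
        site_kind=meta["site_kind"],
        window_spec=tuple(np.asarray(offsets)[order]),
        freqs=np.asarray(rows, dtype=float)[order],
        core_positions=core,
    )


@dataclass
class MatrixLibrary:
    """A named collection of matrices, e.g. GT/GC/AT donor and AG/AC acceptor sets."""

    matrices: dict[str, PWMatrix] = field(default_factory=dict)

    def add(self, m: PWMatrix) -> None:
        if m.name in self.matrices:
            raise MatrixSchemaError(f"duplicate matrix name {m.name!r}")
        self.matrices[m.name] = m

    def __getitem__(self, name: str) -> PWMatrix:
        return self.matrices[name]

    def __iter__(self) -> Iterator[PWMatrix]:
        return iter(self.matrices.values())

    def __len__(self) -> int:
        return len(self.matrices)

    def for_kind(self, site_kind: str) -> list[PWMatrix]:
        return [m for m in self if m.site_kind == site_kind]

    def validate(self) -> None:
        kinds = {m.site_kind for m in self}
        if not {"donor", "acceptor"} <= kinds:
            raise MatrixSchemaError("library needs at least one donor and one acceptor matrix")


def default_library() -> MatrixLibrary:
    """The bundled consensus-value matrices (canonical GT/AG plus the
    non-canonical GC/AT donor and AC acceptor core variants)."""
    lib = MatrixLibrary()
    root = resources.files("splicedelta").joinpath("data/matrices")
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".tsv"):
            lib.add(_matrix_from_tsv(entry.read_text(), entry.name))
    lib.validate()
    return lib
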