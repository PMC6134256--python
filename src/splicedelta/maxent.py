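"""Maximum-entropy splice-site models (MES-style) and signal/decoy log-odds.

The model is the highest-entropy probability distribution over fixed-length
k-mers whose low-order marginals (single positions, adjacent pairs, or any
position subsets) match those estimated from a training set. It is fitted by
iterative proportional fitting (generalized iterative scaling), which for
consistent constraints converges to the unique maximum-entropy solution.
Sequences are scored as log2( P_signal / P_decoy ), an unbounded score in
bits; the canonical spans are a 9-mer (-3..+6) for donors and a 23-mer
(-20..+3) for acceptors.

Full joint tables are enumerable up to L = 9 (4^9 k-mers). Longer windows
use an overlapping-fragment chain: each fragment carries its own full model
and the chained probability

    P(w) = P_1(frag_1) * prod_{i>=2} P_i(frag_i) / P_i(overlap_i)

is exactly normalized because each ratio is a proper conditional of model i.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pwm import encode

__all__ = [
    "MarginalConstraint",
    "MEMModel",
    "FragmentChainModel",
    "TrainingSet",
    "FitError",
    "ModelSchemaError",
    "empirical_marginals",
    "fit_mem",
    "score_log_odds",
    "save_model",
    "load_model",
    "train_from_kmers",
    "adjacent_pair_spec",
]

BASES = "ACGT"


class FitError(RuntimeError):
    """Iterative scaling failed to reach the residual tolerance."""

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class ModelSchemaError(ValueError):
    """Raised for malformed model files."""


@dataclass(frozen=True)
class TrainingSet:
    """Aligned signal and decoy k-mers for one window."""

    signal: tuple[str, ...]
    decoy: tuple[str, ...]
    window_spec: tuple[int, ...]

    def __post_init__(self):
        L = len(self.window_spec)
        for group in (self.signal, self.decoy):
            for kmer in group:
                if len(kmer) != L:
                    raise ValueError(f"k-mer {kmer!r} length != window length {L}")
                if not set(kmer) <= set(BASES):
                    raise ValueError(f"non-ACGT k-mer {kmer!r}")


@dataclass(frozen=True)
class MarginalConstraint:
    """An empirical joint distribution over an ordered subset of positions."""

    positions: tuple[int, ...]  # 0-based indices into the window, ascending
    table: np.ndarray  # shape (4,)*len(positions), sums to 1

    def __post_init__(self):
        pos = tuple(self.positions)
        if pos != tuple(sorted(set(pos))):
            raise ValueError("constraint positions must be ascending and unique")
        table = np.asarray(self.table, dtype=float)
        if table.shape != (4,) * len(pos):
            raise ValueError(f"table shape {table.shape} != {(4,) * len(pos)}")
        if (table < 0).any() or abs(table.sum() - 1) > 1e-9:
            raise ValueError("constraint table must be a probability table (sum 1, entries >= 0)")
        table = table.copy()
        table.setflags(write=False)
        object.__setattr__(self, "table", table)
        object.__setattr__(self, "positions", pos)


def adjacent_pair_spec(L: int) -> list[tuple[int, ...]]:
    """All single positions plus adjacent pairs — the default constraint set."""
    return [(i,) for i in range(L)] + [(i, i + 1) for i in range(L - 1)]


def empirical_marginals(
    kmers: Sequence[str],
    spec: Sequence[Sequence[int]],
    pseudocount: float = 0.0,
) -> list[MarginalConstraint]:
    """Empirical marginal tables over the requested position subsets.

    ``pseudocount`` is a total prior mass spread uniformly over each table
    (``pseudocount / 4^k`` per cell), so tables of different orders remain
    marginals of one smoothed distribution and stay mutually consistent.
    The default of 0 keeps point-mass marginals exact.
    """
    if not kmers:
        raise ValueError("empty k-mer list")
    codes = np.stack([encode(k) for k in kmers])
    constraints = []
    for positions in spec:
        pos = tuple(positions)
        k = len(pos)
        counts = np.full((4,) * k, float(pseudocount) / 4**k)
        np.add.at(counts, tuple(codes[:, p] for p in pos), 1.0)
        constraints.append(MarginalConstraint(pos, counts / counts.sum()))
    return constraints


@dataclass(frozen=True)
class MEMModel:
    """A fitted maximum-entropy distribution over 4^L k-mers (full table)."""

    window_spec: tuple[int, ...]
    probs: np.ndarray  # shape (4,)*L
    constraints: tuple[MarginalConstraint, ...] = ()
    site_kind: str = ""
    max_residual: float = 0.0
    iterations: int = 0

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        L = len(self.window_spec)
        if probs.shape != (4,) * L:
            raise ValueError(f"probs shape {probs.shape} != {(4,) * L}")
        if abs(probs.sum() - 1) > 1e-8:
            raise ValueError(f"probabilities sum to {probs.sum()!r}, not 1")
        probs = probs.copy()
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "window_spec", tuple(self.window_spec))

    def __len__(self) -> int:
        return len(self.window_spec)

    def prob(self, window: str) -> float:
        idx = encode(window)
        if len(idx) != len(self):
            raise ValueError(f"window length {len(idx)} != model window {len(self)}")
        return float(self.probs[tuple(idx)])

    def marginal(self, positions: Sequence[int]) -> np.ndarray:
        axes = tuple(i for i in range(len(self)) if i not in set(positions))
        return self.probs.sum(axis=axes)

    def entropy(self) -> float:
        p = self.probs[self.probs > 0]
        return float(-(p * np.log2(p)).sum())


def fit_mem(
    constraints: Sequence[MarginalConstraint],
    window_len: int,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    window_spec: Sequence[int] | None = None,
    site_kind: str = "",
) -> MEMModel:
    """Fit the maximum-entropy distribution matching the given marginals.

    Iterative proportional fitting from a uniform start; each sweep rescales
    the joint so one constraint's marginal is matched exactly, and the
    procedure converges to the max-entropy solution for mutually consistent
    constraints. Raises :class:`FitError` (carrying the residual) when the
    max marginal residual is still above ``tol`` after ``max_iter`` sweeps.
    """
    L = int(window_len)
    if window_spec is None:
        window_spec = tuple(range(1, L + 1))
    p = np.full((4,) * L, 4.0 ** -L)
    residual = 0.0
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for c in constraints:
            axes = tuple(i for i in range(L) if i not in c.positions)
            marg = p.sum(axis=axes)
            ratio = np.divide(c.table, marg, out=np.zeros_like(marg), where=marg > 0)
            shape = [1] * L
            for pos in c.positions:
                shape[pos] = 4
            p = p * ratio.reshape(shape)
        residual = 0.0
        for c in constraints:
            axes = tuple(i for i in range(L) if i not in c.positions)
            residual = max(residual, float(np.abs(p.sum(axis=axes) - c.table).max()))
        if residual <= tol:
            break
    else:
        raise FitError(
            f"iterative scaling did not converge in {max_iter} sweeps "
            f"(max marginal residual {residual:.3g} > tol {tol:g})",
            residual=residual,
            iterations=max_iter,
        )
    return MEMModel(
        window_spec=tuple(window_spec),
        probs=p / p.sum(),
        constraints=tuple(constraints),
        site_kind=site_kind,
        max_residual=residual,
        iterations=iterations,
    )


@dataclass(frozen=True)
class FragmentChainModel:
    """Ratio-composed chain of overlapping full models for long windows.

    ``fragments`` are (start_index, model) pairs tiling the window in order;
    each fragment after the first divides out its own marginal over the
    positions it shares with the previous fragments, so the chained
    probability sums to 1 exactly.
    """

    window_spec: tuple[int, ...]
    fragments: tuple[tuple[int, MEMModel], ...]
    site_kind: str = ""

    def __post_init__(self):
        L = len(self.window_spec)
        starts = [s for s, _ in self.fragments]
        if starts != sorted(starts) or starts[0] != 0:
            raise ValueError("fragments must tile the window in ascending order from 0")
        covered = 0
        for s, m in self.fragments:
            if s > covered:
                raise ValueError("fragment chain leaves a gap")
            covered = max(covered, s + len(m))
        if covered != L:
            raise ValueError(f"fragments cover {covered} positions, window has {L}")
        object.__setattr__(self, "window_spec", tuple(self.window_spec))
        object.__setattr__(self, "fragments", tuple(self.fragments))

    def __len__(self) -> int:
        return len(self.window_spec)

    def log2_prob(self, window: str) -> float:
        if len(window) != len(self):
            raise ValueError(f"window length {len(window)} != model window {len(self)}")
        total = 0.0
        prev_end = 0
        for s, m in self.fragments:
            frag = window[s : s + len(m)]
            p = m.prob(frag)
            total += math.log2(p) if p > 0 else -math.inf
            if s < prev_end:  # divide out this model's marginal over the overlap
                overlap_positions = tuple(range(0, prev_end - s))
                marg = m.marginal(overlap_positions)
                q = float(marg[tuple(encode(window[s:prev_end]))])
                total -= math.log2(q) if q > 0 else -math.inf
            prev_end = s + len(m)
        return total

    def prob(self, window: str) -> float:
        return float(2.0 ** self.log2_prob(window))


def score_log_odds(signal, decoy, window: str) -> float:
    """log2( P_signal(window) / P_decoy(window) ), in bits.

    Unbounded; may be +/-inf if a model assigns probability 0 (avoidable by
    training with a positive pseudo-count).
    """
    if len(signal) != len(window) or len(decoy) != len(window):
        raise ValueError("window length must match both models")
    ps, pd = signal.prob(window), decoy.prob(window)
    if ps > 0 and pd > 0:
        return float(math.log2(ps) - math.log2(pd))
    if ps == 0 and pd == 0:
        return 0.0
    return math.inf if pd == 0 else -math.inf


def train_from_kmers(
    kmers: Sequence[str],
    window_spec: Sequence[int],
    constraint_spec: Sequence[Sequence[int]] | str = "singles+adjacent",
    pseudocount: float = 0.0,
    fragment_length: int | None = None,
    fragment_overlap: int = 2,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    site_kind: str = "",
):
    """Fit a model (full table, or fragment chain for long windows) from k-mers.

    Windows longer than 9 positions (or when ``fragment_length`` is given)
    are fitted as an overlapping-fragment chain with the default fragment
    length of 7.
    """
    L = len(window_spec)
    if fragment_length is None and L > 9:
        fragment_length = 7

    def resolve_spec(length: int):
        if constraint_spec == "singles+adjacent":
            return adjacent_pair_spec(length)
        if constraint_spec == "singles":
            return [(i,) for i in range(length)]
        return constraint_spec

    if fragment_length is None or fragment_length >= L:
        constraints = empirical_marginals(kmers, resolve_spec(L), pseudocount)
        return fit_mem(constraints, L, tol, max_iter, window_spec, site_kind)
    f, o = fragment_length, fragment_overlap
    starts = list(range(0, L - f, f - o)) + [L - f]
    starts = sorted(set(starts))
    fragments = []
    for s in starts:
        sub = [k[s : s + f] for k in kmers]
        constraints = empirical_marginals(sub, resolve_spec(f), pseudocount)
        fragments.append((s, fit_mem(constraints, f, tol, max_iter, window_spec[s : s + f], site_kind)))
    return FragmentChainModel(tuple(window_spec), tuple(fragments), site_kind)


# ---------------------------------------------------------------------------
# serialization


def save_model(model, path) -> None:
    """Write a model (full or fragment chain) as JSON."""
    if isinstance(model, MEMModel):
        doc = {
            "type": "full",
            "window_spec": list(model.window_spec),
            "site_kind": model.site_kind,
            "probs": np.asarray(model.probs).ravel().tolist(),
        }
    elif isinstance(model, FragmentChainModel):
        doc = {
            "type": "fragment_chain",
            "window_spec": list(model.window_spec),
            "site_kind": model.site_kind,
            "fragments": [
                {
                    "start": s,
                    "window_spec": list(m.window_spec),
                    "probs": np.asarray(m.probs).ravel().tolist(),
                }
                for s, m in model.fragments
            ],
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(doc, fh)


def _table_from_list(values, L: int, label: str) -> np.ndarray:
    probs = np.asarray(values, dtype=float)
    if probs.size != 4**L:
        raise ModelSchemaError(f"{label}: expected {4**L} probabilities, found {probs.size}")
    total = probs.sum()
    if abs(total - 1) > 1e-3:
        raise ModelSchemaError(f"{label}: probabilities sum to {total:.6f} (tolerance 1e-3)")
    if abs(total - 1) > 1e-12:
        import warnings

        warnings.warn(f"{label}: renormalizing probabilities (sum {total:.6f})", stacklevel=3)
        probs = probs / total
    return probs.reshape((4,) * L)


def load_model(path):
    """Load a model written by :func:`save_model` or an external probability
    table in the same schema (renormalized, with a warning, within 1e-3)."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise ModelSchemaError(f"{path}: unreadable model file ({exc})") from exc
    try:
        kind = doc["type"]
        spec = tuple(doc["window_spec"])
        if kind == "full":
            probs = _table_from_list(doc["probs"], len(spec), str(path))
            return MEMModel(spec, probs, site_kind=doc.get("site_kind", ""))
        if kind == "fragment_chain":
            fragments = []
            for frag in doc["fragments"]:
                fspec = tuple(frag["window_spec"])
                probs = _table_from_list(frag["probs"], len(fspec), str(path))
                fragments.append((int(frag["start"]), MEMModel(fspec, probs)))
            return FragmentChainModel(spec, tuple(fragments), doc.get("site_kind", ""))
        raise ModelSchemaError(f"{path}: unknown model type {kind!r}")
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ModelSchemaError):
            raise
        raise ModelSchemaError(f"{path}: malformed model file ({exc})") from exc
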