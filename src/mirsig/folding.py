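"""RNA secondary-structure engine.

The default engine is a simplified base-pair energy model (GC = -3.0,
AU = -2.0, GU = -1.0 kcal/mol per pair, minimum hairpin loop of 3 nt)
solved exactly:

* minimum free energy structure by interval dynamic programming
  (Nussinov-style recursion over pair energies), with deterministic
  tie-breaking (fewer pairs first, then lexicographically smallest
  dot-bracket);
* ensemble base-pair probabilities ``p_ij`` from the Boltzmann partition
  function over the same model, computed by an inside recursion plus its
  adjoint (the McCaskill outside pass), so that
  ``p_ij = q_ij * dZ/dq_ij / Z`` exactly;
* an exhaustive structure enumerator used as an independent reference for
  validating both on short sequences.

The engine is pluggable: anything satisfying :class:`FoldingBackend` (e.g.
an adapter around a full nearest-neighbor thermodynamic folder) can stand
in for :class:`BuiltinBackend`. Descriptor cutoff ranges are a property of
the backend's energy scale and must be re-derived per backend.

Hot loops are JIT-compiled with numba; the first fold in a process pays a
one-off compilation cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Protocol

import numpy as np
from numba import njit

__all__ = [
    "FoldingParams",
    "FoldingProfile",
    "DuplexReport",
    "FoldingBackend",
    "BuiltinBackend",
    "fold_mfe",
    "pair_probabilities",
    "fold_profile",
    "analyze_duplex",
    "pair_table",
    "enumerate_structures",
    "ensemble_from_enumeration",
]

_BASES = "ACGU"
_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class FoldingParams:
    """Energy model parameters.

    ``gc``/``au``/``gu`` are per-pair energies in kcal/mol (negative =
    stabilizing); ``min_loop`` is the minimum number of unpaired bases in a
    hairpin loop; ``rt`` is the Boltzmann factor denominator in kcal/mol.
    """

    gc: float = -3.0
    au: float = -2.0
    gu: float = -1.0
    min_loop: int = 3
    rt: float = 0.616
    #: pair probabilities below this are dropped from the sparse map;
    #: negligible for the entropy/distance descriptors at this scale
    prob_min: float = 1e-9

    def energy_matrix(self) -> np.ndarray:
        """4x4 matrix of pair energies indexed by A,C,G,U; +inf = not pairable."""
        e = np.full((4, 4), np.inf)
        for (a, b), val in (
            (("G", "C"), self.gc),
            (("A", "U"), self.au),
            (("G", "U"), self.gu),
        ):
            e[_INDEX[a], _INDEX[b]] = val
            e[_INDEX[b], _INDEX[a]] = val
        return e


DEFAULT_PARAMS = FoldingParams()


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError:
        bad = sorted(set(seq) - set(_BASES))
        raise ValueError(f"invalid RNA characters {bad} in sequence") from None


@dataclass
class FoldingProfile:
    """MFE structure and ensemble pair probabilities for one sequence."""

    seq: str
    structure: str
    mfe: float
    pair_prob: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.seq):
            raise ValueError("structure/sequence length mismatch")


@dataclass
class DuplexReport:
    """Geometry of the mature/miRNA* duplex within a folded precursor."""

    mature_span: tuple[int, int]
    star_span: tuple[int, int]
    n_pairs: int
    mismatches: int
    same_arm: bool
    star_contiguous: bool
    overlaps_loop: bool


class FoldingBackend(Protocol):
    """Contract for a pluggable folding engine."""

    def fold(self, seq: str) -> FoldingProfile: ...


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=False)
def _dp_energy(emat_seq):
    """Interval DP: E[i,j] = min energy on i..j, NP[i,j] = min pairs at E."""
    n = emat_seq.shape[0]
    E = np.zeros((n + 1, n + 1))
    NP = np.zeros((n + 1, n + 1), dtype=np.int64)
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            best_e = E[i + 1, j]
            best_p = NP[i + 1, j]
            for k in range(i + 4, j + 1):
                e_ik = emat_seq[i, k]
                if not np.isfinite(e_ik):
                    continue
                left = E[i + 1, k - 1] if k - 1 >= i + 1 else 0.0
                lp = NP[i + 1, k - 1] if k - 1 >= i + 1 else 0
                right = E[k + 1, j] if k + 1 <= j else 0.0
                rp = NP[k + 1, j] if k + 1 <= j else 0
                e = e_ik + left + right
                p = 1 + lp + rp
                if e < best_e - 1e-9 or (abs(e - best_e) <= 1e-9 and p < best_p):
                    best_e = e
                    best_p = p
            E[i, j] = best_e
            NP[i, j] = best_p
    return E, NP


@njit(cache=False)
def _dp_partition(qmat, inv_s):
    """Inside partition function + adjoint (outside) pass, scaled.

    qmat[i,k] holds the scaled Boltzmann pair weight (0 if unpairable, and
    already divided by sigma^2); inv_s is the per-unpaired-position scale.
    Returns the matrix P of pair probabilities.
    """
    n = qmat.shape[0]
    Z = np.ones((n + 2, n + 2))
    for span in range(1, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            z = inv_s * Z[i + 1, j]
            for k in range(i + 4, j + 1):
                q = qmat[i, k]
                if q > 0.0:
                    z += q * Z[i + 1, k - 1] * Z[k + 1, j]
            Z[i, j] = z
    Zb = np.zeros((n + 2, n + 2))
    Zb[0, n - 1] = 1.0
    qbar = np.zeros((n, n))
    for span in range(n, 0, -1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            b = Zb[i, j]
            if b == 0.0:
                continue
            Zb[i + 1, j] += b * inv_s
            for k in range(i + 4, j + 1):
                q = qmat[i, k]
                if q > 0.0:
                    zl = Z[i + 1, k - 1]
                    zr = Z[k + 1, j]
                    qbar[i, k] += b * zl * zr
                    Zb[i + 1, k - 1] += b * q * zr
                    Zb[k + 1, j] += b * q * zl
    ztot = Z[0, n - 1]
    P = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 4, n):
            if qmat[i, k] > 0.0 and qbar[i, k] > 0.0:
                P[i, k] = qmat[i, k] * qbar[i, k] / ztot
    return P


# ---------------------------------------------------------------------------
# public operations


def _pairwise_energies(seq: str, params: FoldingParams) -> np.ndarray:
    enc = _encode(seq)
    emat = params.energy_matrix()
    n = len(enc)
    out = np.full((n, n), np.inf)
    for i in range(n):
        lo = i + params.min_loop + 1
        if lo < n:
            out[i, lo:] = emat[enc[i], enc[lo:]]
    return out


def fold_mfe(seq: str, params: FoldingParams = DEFAULT_PARAMS) -> tuple[str, float]:
    """Minimum free energy structure under the built-in pair-energy model.

    Ties are broken toward the structure with fewer pairs, then toward the
    lexicographically smallest dot-bracket string, so output is fully
    deterministic.
    """
    if not seq:
        raise ValueError("empty sequence")
    emat_seq = _pairwise_energies(seq, params)
    E, NP = _dp_energy(emat_seq)
    n = len(seq)

    memo: dict[tuple[int, int], str] = {}

    def tb(i: int, j: int) -> str:
        if j < i:
            return ""
        key = (i, j)
        if key in memo:
            return memo[key]
        target_e, target_p = E[i, j], NP[i, j]
        candidates = []
        if abs(E[i + 1, j] - target_e) <= 1e-9 and NP[i + 1, j] == target_p:
            candidates.append("." + tb(i + 1, j))
        for k in range(i + 4, j + 1):
            e_ik = emat_seq[i, k]
            if not math.isfinite(e_ik):
                continue
            e = e_ik + E[i + 1, k - 1] + E[k + 1, j]
            p = 1 + NP[i + 1, k - 1] + NP[k + 1, j]
            if abs(e - target_e) <= 1e-9 and p == target_p:
                candidates.append("(" + tb(i + 1, k - 1) + ")" + tb(k + 1, j))
        best = min(candidates)
        memo[key] = best
        return best

    structure = tb(0, n - 1)
    return structure, float(E[0, n - 1])


def pair_probabilities(
    seq: str, params: FoldingParams = DEFAULT_PARAMS, mfe: float | None = None
) -> dict[tuple[int, int], float]:
    """Ensemble base-pair probabilities p_ij (i < j) under the model.

    p_ij is the Boltzmann-weighted fraction of secondary structures that
    contain pair (i, j), with weights exp(-E/RT). The partition function is
    scaled per position (anchored at the MFE) to stay inside float64 range;
    the scale cancels exactly in the probability ratio.
    """
    if not seq:
        raise ValueError("empty sequence")
    emat_seq = _pairwise_energies(seq, params)
    n = len(seq)
    if mfe is None:
        E, _ = _dp_energy(emat_seq)
        mfe = float(E[0, n - 1])
    sigma = math.exp(-mfe / (n * params.rt))
    inv_s = 1.0 / sigma
    qmat = np.zeros((n, n))
    finite = np.isfinite(emat_seq)
    qmat[finite] = np.exp(-emat_seq[finite] / params.rt) * inv_s * inv_s
    P = _dp_partition(qmat, inv_s)
    out: dict[tuple[int, int], float] = {}
    for i, j in zip(*np.nonzero(P >= params.prob_min)):
        out[(int(i), int(j))] = float(P[i, j])
    return out


def fold_profile(seq: str, params: FoldingParams = DEFAULT_PARAMS) -> FoldingProfile:
    """MFE structure plus ensemble pair probabilities in one call."""
    structure, mfe = fold_mfe(seq, params)
    probs = pair_probabilities(seq, params, mfe=mfe)
    return FoldingProfile(seq=seq, structure=structure, mfe=mfe, pair_prob=probs)


class BuiltinBackend:
    """Default folding backend over the built-in energy model, with a
    bounded fold cache (cleared when ``max_cache`` entries accumulate)."""

    def __init__(self, params: FoldingParams = DEFAULT_PARAMS, max_cache: int = 4096):
        self.params = params
        self.max_cache = max_cache
        self._cache: dict[str, FoldingProfile] = {}

    def fold(self, seq: str) -> FoldingProfile:
        prof = self._cache.get(seq)
        if prof is None:
            prof = fold_profile(seq, self.params)
            if len(self._cache) >= self.max_cache:
                self._cache.clear()
            self._cache[seq] = prof
        return prof


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 = unpaired) from a dot-bracket string."""
    stack: list[int] = []
    pt = [-1] * len(structure)
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pt


def _terminal_loops(pt: list[int]) -> list[tuple[int, int]]:
    """Half-open spans of hairpin (terminal) loops: unpaired stretches
    directly closed by a pair with nothing paired inside."""
    loops = []
    for i, j in enumerate(pt):
        if j > i and all(pt[k] == -1 for k in range(i + 1, j)):
            loops.append((i + 1, j))
    return loops


def analyze_duplex(profile: FoldingProfile, mature_span: tuple[int, int]) -> DuplexReport:
    """Describe the mature/star duplex geometry within a folded precursor.

    ``n_pairs`` counts mature positions paired to a partner outside the
    mature span; ``mismatches`` is mature length minus n_pairs (unpaired or
    self-paired mature positions). ``star_contiguous`` is False when any
    position inside the star span pairs outside the mature span (a break or
    side-loop in the star). A mature with no external partners has no
    locatable star: same_arm and star_contiguous are reported False.
    """
    ms, me = mature_span
    if me <= ms:
        raise ValueError("empty mature span")
    if ms < 0 or me > len(profile.seq):
        raise ValueError("mature span outside precursor bounds")
    pt = pair_table(profile.structure)
    partners = [pt[p] for p in range(ms, me) if pt[p] >= 0 and not (ms <= pt[p] < me)]
    n_pairs = len(partners)
    mismatches = (me - ms) - n_pairs
    if partners:
        star_span = (min(partners), max(partners) + 1)
        same_arm = all(p < ms for p in partners) or all(p >= me for p in partners)
        star_contiguous = all(
            pt[s] < 0 or (ms <= pt[s] < me) for s in range(star_span[0], star_span[1])
        )
    else:
        star_span = (0, 0)
        same_arm = False
        star_contiguous = False
    overlaps_loop = any(
        ms < le and lo < me for lo, le in _terminal_loops(pt)
    )
    return DuplexReport(
        mature_span=mature_span,
        star_span=star_span,
        n_pairs=n_pairs,
        mismatches=mismatches,
        same_arm=same_arm,
        star_contiguous=star_contiguous,
        overlaps_loop=overlaps_loop,
    )


# ---------------------------------------------------------------------------
# exhaustive reference (independent of the DP path; practical for len <= ~20)


def enumerate_structures(
    seq: str, params: FoldingParams = DEFAULT_PARAMS
) -> Iterator[tuple[frozenset[tuple[int, int]], float]]:
    """Yield every secondary structure (as a set of pairs) with its energy.

    Plain recursive enumeration over non-crossing pair sets honoring the
    complementarity and minimum-loop constraints. Exponential; intended as
    an exhaustive reference for short sequences.
    """
    emat_seq = _pairwise_energies(seq, params)
    n = len(seq)

    def rec(i: int, j: int) -> list[list[tuple[int, int]]]:
        if j < i:
            return [[]]
        out = [s for s in rec(i + 1, j)]
        for k in range(i + 4, j + 1):
            if math.isfinite(emat_seq[i, k]):
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append([(i, k)] + left + right)
        return out

    for pairs in rec(0, n - 1):
        energy = sum(emat_seq[i, j] for i, j in pairs)
        yield frozenset(pairs), float(energy)


def ensemble_from_enumeration(
    seq: str, params: FoldingParams = DEFAULT_PARAMS
) -> tuple[float, dict[tuple[int, int], float]]:
    """(MFE, Boltzmann pair probabilities) by brute-force enumeration."""
    structures = list(enumerate_structures(seq, params))
    mfe = min(e for _, e in structures)
    total = 0.0
    acc: dict[tuple[int, int], float] = {}
    for pairs, e in structures:
        w = math.exp(-(e - mfe) / params.rt)
        total += w
        for pr in pairs:
            acc[pr] = acc.get(pr, 0.0) + w
    return mfe, {pr: w / total for pr, w in acc.items()}
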