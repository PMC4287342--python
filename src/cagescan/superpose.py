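"""Rigid-body superposition, iterative core trimming and internal symmetry.

The superposition protocol used throughout: optimal least-squares (Kabsch)
fit on the currently paired C-alpha positions, discard pairs deviating by
more than a cutoff (default 3.5 A), re-fit, iterate to a fixed point.  The
surviving pairs are the "core"; the reported RMSD is over the core only.
Seed pairings for homologous domains come from a global sequence alignment
(BLOSUM62, affine gap penalties 11/1) of the C-alpha traces, or from a
caller-supplied residue mapping.

``internal_symmetry`` measures the approximate two-fold symmetry of a
domain built from two sequence-consecutive halves (e.g. two beta-meanders):
it slides one half against the other over all sequence registers and
reports the best trimmed-core superposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import Residue, Structure

__all__ = [
    "SuperpositionResult",
    "SymmetrySplit",
    "CaTrace",
    "kabsch",
    "core_superpose",
    "align_traces",
    "superpose_traces",
    "internal_symmetry",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid map P -> R @ P + t onto Q, with its trimmed core."""

    rotation: np.ndarray          # (3, 3), det +1
    translation: np.ndarray       # (3,)
    rmsd: float                   # A, over the core pairs
    core_pairs: list[tuple[int, int]]
    n_core: int

    def transform(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class SymmetrySplit:
    """Two disjoint residue-index ranges (half-open) within one trace."""

    half_a: tuple[int, int]
    half_b: tuple[int, int]

    def __post_init__(self):
        (a0, a1), (b0, b1) = self.half_a, self.half_b
        if not (a0 < a1 and b0 < b1):
            raise ValueError("empty half in symmetry split")
        if max(a0, b0) < min(a1, b1):
            raise ValueError("symmetry split halves overlap")

    @classmethod
    def at(cls, split: int, n: int) -> "SymmetrySplit":
        return cls((0, split), (split, n))


class CaTrace:
    """C-alpha trace of one chain: residues, one-letter sequence, coordinates."""

    def __init__(self, residues: list[Residue]):
        from Bio.SeqUtils import seq1

        self.residues = [r for r in residues if any(a.name == "CA" for a in r.atoms)]
        self.coords = np.array([r.atom("CA").coords for r in self.residues], float)
        self.seq = "".join(
            (seq1(r.name.capitalize()) or "X") if len(r.name) == 3 else "X"
            for r in self.residues
        ).upper().replace("-", "X")

    def __len__(self) -> int:
        return len(self.residues)

    @classmethod
    def from_structure(cls, s: Structure, chain_id: str | None = None,
                       model_index: int = 0) -> "CaTrace":
        chains = s.chains(model_index)
        if chain_id is None:
            chain_id = sorted(chains)[0]
        if chain_id not in chains:
            raise KeyError(f"{s.pdb_id}: no chain {chain_id!r}")
        return cls([r for r in chains[chain_id] if not r.is_hetatm])


def kabsch(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of paired point sets.

    Returns R, t minimising sum ||R p_i + t - q_i||^2 and the RMSD at the
    optimum.  Requires n >= 3 non-degenerate (non-collinear) points.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("kabsch: point sets must both be (n, 3)")
    n = len(P)
    if n < 3:
        raise ValueError(f"kabsch: need at least 3 points, got {n}")
    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
    sv_p = np.linalg.svd(Pc, compute_uv=False)
    sv_q = np.linalg.svd(Qc, compute_uv=False)
    scale = max(sv_p[0], sv_q[0], 1e-12)
    if sv_p[1] / scale < 1e-8 or sv_q[1] / scale < 1e-8:
        raise ValueError("kabsch: degenerate (collinear or coincident) input")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rot, _ = Rotation.align_vectors(Qc, Pc)
    R = rot.as_matrix()
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    # recompute the residual directly: scipy's rssd loses precision near 0
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               core_pairs=[(i, i) for i in range(n)], n_core=n)


def core_superpose(P: np.ndarray, Q: np.ndarray,
                   seed_pairs: list[tuple[int, int]] | None = None,
                   trim_cutoff: float = 3.5, min_core: int = 10,
                   max_iter: int = 100) -> SuperpositionResult:
    """Iteratively trimmed superposition: fit, drop pairs deviating by more
    than ``trim_cutoff``, re-fit, until the pair set is stable.

    ``seed_pairs`` maps indices of P onto indices of Q (default: identity,
    requiring equal lengths).  Raises if the core shrinks below
    ``min_core`` -- no superimposable core.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if seed_pairs is None:
        if len(P) != len(Q):
            raise ValueError("identity pairing needs equally long traces")
        pairs = [(i, i) for i in range(len(P))]
    else:
        pairs = [(int(i), int(j)) for i, j in seed_pairs]
    if len(pairs) < min_core:
        raise ValueError(f"need at least {min_core} seed pairs, got {len(pairs)}")

    current = pairs
    result = None
    for _ in range(max_iter):
        pi = np.array([i for i, _ in current])
        qi = np.array([j for _, j in current])
        result = kabsch(P[pi], Q[qi])
        moved = result.transform(P[pi])
        dev = np.linalg.norm(moved - Q[qi], axis=1)
        kept = [p for p, d in zip(current, dev) if d <= trim_cutoff]
        if len(kept) < min_core:
            raise ValueError(
                f"no superimposable core: {len(kept)} pairs survive the "
                f"{trim_cutoff} A cutoff (need {min_core})"
            )
        if kept == current:
            break
        current = kept
    pi = np.array([i for i, _ in current])
    qi = np.array([j for _, j in current])
    final = kabsch(P[pi], Q[qi])
    return SuperpositionResult(rotation=final.rotation, translation=final.translation,
                               rmsd=final.rmsd, core_pairs=list(current),
                               n_core=len(current))


def align_traces(a: CaTrace, b: CaTrace) -> list[tuple[int, int]]:
    """Seed pairing from a global sequence alignment of the two traces
    (BLOSUM62, gap open 11, extend 1)."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    aln = aligner.align(a.seq, b.seq)[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def superpose_traces(a: CaTrace, b: CaTrace,
                     seed_pairs: list[tuple[int, int]] | None = None,
                     trim_cutoff: float = 3.5, min_core: int = 10) -> SuperpositionResult:
    """Align (if no pairing given), then iteratively trim and superpose."""
    if seed_pairs is None:
        seed_pairs = align_traces(a, b)
    return core_superpose(a.coords, b.coords, seed_pairs,
                          trim_cutoff=trim_cutoff, min_core=min_core)


def internal_symmetry(trace: CaTrace | np.ndarray, split: SymmetrySplit | int,
                      trim_cutoff: float = 3.5, min_core: int = 10,
                      min_overlap: int = 15) -> SuperpositionResult:
    """Best trimmed superposition of one half of a domain onto the other,
    over all sequence registers.

    ``split`` is a :class:`SymmetrySplit` or an integer split point (first
    half = [0, split), second = [split, end)).  Both halves must offer at
    least ``min_overlap`` residues.  Pairs in the result are indices into
    the full trace.  The register maximising the core size wins; ties go to
    the lower RMSD.
    """
    coords = trace.coords if isinstance(trace, CaTrace) else np.asarray(trace, float)
    if isinstance(split, int):
        split = SymmetrySplit.at(split, len(coords))
    (a0, a1), (b0, b1) = split.half_a, split.half_b
    if a1 > len(coords) or b1 > len(coords):
        raise ValueError("symmetry split exceeds trace length")
    A = coords[a0:a1]
    B = coords[b0:b1]
    if len(A) < min_overlap or len(B) < min_overlap:
        raise ValueError(f"both halves need >= {min_overlap} residues")

    best: SuperpositionResult | None = None
    for offset in range(-(len(A) - min_overlap), len(B) - min_overlap + 1):
        lo = max(0, -offset)
        hi = min(len(A), len(B) - offset)
        if hi - lo < min_overlap:
            continue
        pairs = [(i, i + offset) for i in range(lo, hi)]
        try:
            res = core_superpose(A, B, pairs, trim_cutoff=trim_cutoff,
                                 min_core=min_core)
        except ValueError:
            continue
        if best is None or (res.n_core, -res.rmsd) > (best.n_core, -best.rmsd):
            best = res
    if best is None:
        raise ValueError("no superimposable core at any register")
    best.core_pairs = [(a0 + i, b0 + j) for i, j in best.core_pairs]
    return best
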