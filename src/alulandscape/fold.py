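"""Base-pair-maximization RNA folding for duplex verification.

A Nussinov-style dynamic program maximizes a weighted count of canonical
base pairs (GC=3, AU=2, GU=1 by default) subject to nesting and a minimum
hairpin-loop length.  Two-sequence cofolding concatenates the strands
across a non-pairing linker, the standard trick for duplex prediction, and
reports which fraction of the optimal structure's pairs is intermolecular.

This is a desk-scale surrogate for nearest-neighbor thermodynamic folding:
it does not produce free energies, but it cleanly separates the strong
intermolecular pairing of an inverted-repeat pair from the weak
self-structure of same-orientation controls, which is the property the
duplex verdict needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["FoldParams", "FoldResult", "nussinov_fold", "cofold", "duplex_report"]

_RNA_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_LINKER_CODE = 4  # sentinel: never pairs


@dataclass(frozen=True)
class FoldParams:
    """Folding objective parameters.

    ``min_hairpin`` is the minimum number of unpaired bases enclosed by a
    hairpin-closing pair; ``pair_scores`` weight GC/AU/GU pairs;
    ``linker_length`` is the non-pairing spacer used by cofolding and must
    be at least ``min_hairpin`` so cross-linker pairs are unconstrained.
    """

    min_hairpin: int = 3
    pair_scores: dict = field(
        default_factory=lambda: {"GC": 3, "AU": 2, "GU": 1}
    )
    linker_length: int = 10

    def __post_init__(self) -> None:
        if self.min_hairpin < 0:
            raise ValueError("min_hairpin must be >= 0")
        if self.linker_length < self.min_hairpin:
            raise ValueError("linker_length must be >= min_hairpin")
        if any(v <= 0 for v in self.pair_scores.values()):
            raise ValueError("pair scores must be positive")

    def score_matrix(self) -> np.ndarray:
        mat = np.zeros((5, 5), dtype=np.int32)
        for pair, score in self.pair_scores.items():
            i, j = _RNA_CODE[pair[0]], _RNA_CODE[pair[1]]
            mat[i, j] = mat[j, i] = score
        return mat


@dataclass(frozen=True)
class FoldResult:
    """One optimal structure in dot-bracket form."""

    sequence: str  # RNA alphabet; concatenated strands for cofold
    structure: str
    pairs: tuple[tuple[int, int], ...]
    n_pairs: int
    score: int
    cut_point: int | None = None  # first index of strand B (cofold only)
    intermolecular_fraction: float | None = None


def _encode(seq: str, label: str = "sequence") -> np.ndarray:
    rna = seq.upper().replace("T", "U")
    try:
        return np.array([_RNA_CODE[b] for b in rna], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"{label} contains non-RNA character {exc.args[0]!r}") from None


@njit(cache=True)
def _fill(codes, pair_mat, min_hairpin):  # pragma: no cover - numba kernel
    n = len(codes)
    W = np.zeros((n + 1, n + 1), dtype=np.int32)
    for span in range(min_hairpin + 1, n):
        for i in range(n - span):
            j = i + span
            best = W[i + 1, j]
            for k in range(i + min_hairpin + 1, j + 1):
                ps = pair_mat[codes[i], codes[k]]
                if ps > 0:
                    v = ps + W[i + 1, k - 1] + W[k + 1, j]
                    if v > best:
                        best = v
            W[i, j] = best
    return W


def _traceback(W, codes, pair_mat, min_hairpin) -> list[tuple[int, int]]:
    """Deterministic traceback: pair i with the smallest optimal partner."""
    pairs: list[tuple[int, int]] = []
    stack = [(0, len(codes) - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or W[i, j] == 0:
            continue
        for k in range(i + min_hairpin + 1, j + 1):
            ps = pair_mat[codes[i], codes[k]]
            if ps > 0 and W[i, j] == ps + W[i + 1, k - 1] + W[k + 1, j]:
                pairs.append((i, k))
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                break
        else:
            stack.append((i + 1, j))
    return sorted(pairs)


def _fold_codes(codes: np.ndarray, params: FoldParams):
    if len(codes) == 0:
        return [], 0
    mat = params.score_matrix()
    W = _fill(codes, mat, params.min_hairpin)
    pairs = _traceback(W, codes, mat, params.min_hairpin)
    return pairs, int(W[0, len(codes) - 1])


def nussinov_fold(sequence: str, params: FoldParams = FoldParams()) -> FoldResult:
    """Optimal weighted base-pair structure of a single sequence.

    T is read as U; output is always on the RNA alphabet.
    """
    codes = _encode(sequence)
    pairs, score = _fold_codes(codes, params)
    structure = ["."] * len(codes)
    for i, j in pairs:
        structure[i], structure[j] = "(", ")"
    rna = sequence.upper().replace("T", "U")
    return FoldResult(
        sequence=rna,
        structure="".join(structure),
        pairs=tuple(pairs),
        n_pairs=len(pairs),
        score=score,
    )


def cofold(seq_a: str, seq_b: str, params: FoldParams = FoldParams()) -> FoldResult:
    """Joint structure of two strands joined by a non-pairing linker.

    The returned coordinates refer to the concatenation A+B with the linker
    removed; ``cut_point`` is the first index of strand B and the
    intermolecular fraction is the share of pairs spanning the cut.
    """
    if not seq_a or not seq_b:
        raise ValueError("cofold requires two non-empty sequences")
    a = _encode(seq_a, "seq_a")
    b = _encode(seq_b, "seq_b")
    linker = np.full(params.linker_length, _LINKER_CODE, dtype=np.int64)
    codes = np.concatenate([a, linker, b])
    raw_pairs, score = _fold_codes(codes, params)
    cut = len(a)
    L = params.linker_length

    def unlink(idx: int) -> int:
        return idx if idx < cut else idx - L

    pairs = sorted((unlink(i), unlink(j)) for i, j in raw_pairs)
    inter = sum(1 for i, j in pairs if i < cut <= j)
    structure = ["."] * (len(a) + len(b))
    for i, j in pairs:
        structure[i], structure[j] = "(", ")"
    rna = (seq_a + seq_b).upper().replace("T", "U")
    return FoldResult(
        sequence=rna,
        structure="".join(structure),
        pairs=tuple(pairs),
        n_pairs=len(pairs),
        score=score,
        cut_point=cut,
        intermolecular_fraction=inter / len(pairs) if pairs else 0.0,
    )


def duplex_report(
    iralu_pair,
    utr_sequence: str,
    params: FoldParams = FoldParams(),
    intermolecular_threshold: float = 0.5,
    min_pair_factor: float = 0.3,
) -> tuple[FoldResult, bool]:
    """Cofold the two elements of an IRAlu pair and call a duplex verdict.

    The two subsequences are taken from the transcript exactly as they occur
    (no reverse complementation: an antisense element already carries the
    complementary sequence), folded jointly, and judged a duplex when the
    intermolecular fraction reaches ``intermolecular_threshold`` and the
    pair count reaches ``min_pair_factor`` times the shorter element length.
    """
    first, second = sorted(
        (iralu_pair.sense_hit, iralu_pair.antisense_hit), key=lambda h: h.start
    )
    for h in (first, second):
        if h.start < 0 or h.end > len(utr_sequence):
            raise ValueError(f"pair interval [{h.start},{h.end}) outside the UTR")
    seq_a = utr_sequence[first.start : first.end]
    seq_b = utr_sequence[second.start : second.end]
    result = cofold(seq_a, seq_b, params)
    shorter = min(len(seq_a), len(seq_b))
    verdict = (
        result.intermolecular_fraction is not None
        and result.intermolecular_fraction >= intermolecular_threshold
        and result.n_pairs >= min_pair_factor * shorter
    )
    return result, verdict


def write_dot_bracket(result: FoldResult, path) -> None:
    """Sequence line, structure line, score line (cofold marks the cut '&')."""
    seq, struct = result.sequence, result.structure
    if result.cut_point is not None:
        c = result.cut_point
        seq = seq[:c] + "&" + seq[c:]
        struct = struct[:c] + "&" + struct[c:]
    with open(path, "w") as fh:
        fh.write(f"{seq}\n{struct}\n# pairs={result.n_pairs} score={result.score}")
        if result.intermolecular_fraction is not None:
            fh.write(f" intermolecular_fraction={result.intermolecular_fraction:.3f}")
        fh.write("\n")
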