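"""Global pairwise sequence alignment (Needleman–Wunsch with affine gaps).

Used in two places: renumbering structure chains onto reference (UniProt-style)
sequence coordinates, and establishing residue correspondence before rigid
superposition. Scoring defaults to BLOSUM62 with the standard gap penalties
(open 11, extend 1); a gap of length L costs ``gap_open + L * gap_extend``.

The dynamic program is the Gotoh three-state formulation with a fixed
traceback preference (diagonal > up > left, and within gap states
close-the-gap first) so results are fully deterministic.

Positions containing ``X`` (unknown/unmappable residue) score zero against
everything and never count as identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentResult",
    "ResidueMap",
    "AlignmentError",
    "load_matrix",
    "blosum62",
    "global_align",
    "map_chain_to_reference",
]

NEG_INF = float("-inf")


class AlignmentError(ValueError):
    pass


def _to_dict(arr) -> dict[tuple[str, str], float]:
    alpha = arr.alphabet
    return {
        (a, b): float(arr[a, b]) for a in alpha for b in alpha
    }


def load_matrix(path) -> dict[tuple[str, str], float]:
    """Read an NCBI-format substitution matrix file into a pair->score dict."""
    with open(path) as fh:
        return _to_dict(substitution_matrices.read(fh))


_BLOSUM62: dict[tuple[str, str], float] | None = None


def blosum62() -> dict[tuple[str, str], float]:
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = _to_dict(substitution_matrices.load("BLOSUM62"))
    return _BLOSUM62


@dataclass
class AlignmentResult:
    """A global alignment: gapped strings, score, matched position pairs."""

    aligned_a: str
    aligned_b: str
    score: float
    pairs: list[tuple[int, int]]  # 1-based matched positions
    identity: float  # over matched positions; X never identical

    def __post_init__(self) -> None:
        assert len(self.aligned_a) == len(self.aligned_b)


@dataclass
class ResidueMap:
    """Chain residue key <-> reference sequence position correspondence."""

    chain_id: str
    #: (residue_key, reference position, letters identical?)
    entries: list[tuple[tuple[str, int, str], int, bool]]
    identity: float
    unmapped_keys: list[tuple[str, int, str]] = field(default_factory=list)

    def key_for_position(self, pos: int) -> tuple[str, int, str] | None:
        for key, p, _ in self.entries:
            if p == pos:
                return key
        return None

    def position_for_key(self, key: tuple[str, int, str]) -> int | None:
        for k, p, _ in self.entries:
            if k == key:
                return p
        return None

    def position_to_key(self) -> dict[int, tuple[str, int, str]]:
        return {p: k for k, p, _ in self.entries}


def _pair_score(a: str, b: str, matrix: dict[tuple[str, str], float]) -> float:
    if a == "X" or b == "X":
        return 0.0
    try:
        return matrix[(a, b)]
    except KeyError:
        return matrix.get((b, a), 0.0)


def _sanitize(seq: str, label: str) -> str:
    if not seq:
        raise AlignmentError(f"{label}: empty sequence")
    seq = seq.upper()
    known = set("ACDEFGHIKLMNPQRSTVWYBZX*")
    out = []
    for c in seq:
        if c not in known:
            logger.warning("unknown letter %r in %s treated as X", c, label)
            c = "X"
        out.append(c)
    return "".join(out)


def global_align(
    a: str,
    b: str,
    matrix: dict[tuple[str, str], float] | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences, affine gaps.

    A gap of length L is penalized ``gap_open + L*gap_extend`` (BLAST
    convention); terminal gaps are penalized like internal ones.
    """
    a = _sanitize(a, "sequence a")
    b = _sanitize(b, "sequence b")
    if matrix is None:
        matrix = blosum62()
    n, m = len(a), len(b)

    # Three-state Gotoh. M = a[i] aligned to b[j]; Ix = gap in b (consume a,
    # "up"); Iy = gap in a (consume b, "left"). Opening costs gap_open +
    # gap_extend for the first gapped position.
    open_cost = gap_open + gap_extend
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    # traceback pointers: state char of the predecessor
    ptrM = [[""] * (m + 1) for _ in range(n + 1)]
    ptrX = [[""] * (m + 1) for _ in range(n + 1)]
    ptrY = [[""] * (m + 1) for _ in range(n + 1)]

    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -(gap_open + i * gap_extend)
        ptrX[i][0] = "M" if i == 1 else "X"
    for j in range(1, m + 1):
        Iy[0][j] = -(gap_open + j * gap_extend)
        ptrY[0][j] = "M" if j == 1 else "Y"

    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = Ix[i], Ix[i - 1]
        Yi = Iy[i]
        Yi1 = Iy[i - 1]
        for j in range(1, m + 1):
            s = _pair_score(ai, b[j - 1], matrix)
            # M: best predecessor at (i-1, j-1); tie order M > Ix > Iy
            best, state = Mi1[j - 1], "M"
            if Xi1[j - 1] > best:
                best, state = Xi1[j - 1], "X"
            if Yi1[j - 1] > best:
                best, state = Yi1[j - 1], "Y"
            Mi[j] = best + s
            ptrM[i][j] = state
            # Ix ("up"): gap in b; prefer closing (from M) on ties
            o, e = Mi1[j] - open_cost, Xi1[j] - gap_extend
            if o >= e:
                Xi[j], ptrX[i][j] = o, "M"
            else:
                Xi[j], ptrX[i][j] = e, "X"
            # Iy ("left"): gap in a
            o, e = Mi[j - 1] - open_cost, Yi[j - 1] - gap_extend
            if o >= e:
                Yi[j], ptrY[i][j] = o, "M"
            else:
                Yi[j], ptrY[i][j] = e, "Y"

    # final state preference: M (diagonal) > Ix (up) > Iy (left)
    score, state = M[n][m], "M"
    if Ix[n][m] > score:
        score, state = Ix[n][m], "X"
    if Iy[n][m] > score:
        score, state = Iy[n][m], "Y"

    out_a: list[str] = []
    out_b: list[str] = []
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            prev = ptrM[i][j]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            pairs.append((i, j))
            i, j = i - 1, j - 1
        elif state == "X":
            prev = ptrX[i][j]
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            prev = ptrY[i][j]
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        state = prev
    pairs.reverse()
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))

    ident = 0
    for pa, pb in pairs:
        ca, cb = a[pa - 1], b[pb - 1]
        if ca == cb and ca != "X":
            ident += 1
    identity = ident / len(pairs) if pairs else 0.0
    return AlignmentResult(aligned_a, aligned_b, score, pairs, identity)


def map_chain_to_reference(
    chain_seq,
    ref_seq: str,
    matrix: dict[tuple[str, str], float] | None = None,
    identity_floor: float = 0.30,
) -> ResidueMap:
    """Map a structure chain's residues onto reference-sequence numbering.

    ``chain_seq`` is a :class:`~ptmbind.structures_io.ChainSequence`.
    An alignment identity below ``identity_floor`` raises — the chain is
    probably chimeric or aligned to the wrong reference, the cases the
    annotation stage must exclude rather than renumber.
    """
    aln = global_align(chain_seq.sequence, ref_seq, matrix=matrix)
    if aln.identity < identity_floor:
        raise AlignmentError(
            f"chain {chain_seq.chain_id}: identity {aln.identity:.2f} to the "
            f"reference is below the floor {identity_floor:.2f} — probable "
            "chimeric chain or wrong reference sequence"
        )
    entries = []
    mapped_keys = set()
    for pos_chain, pos_ref in aln.pairs:
        key = chain_seq.index[pos_chain]
        ca = chain_seq.sequence[pos_chain - 1]
        cr = ref_seq[pos_ref - 1].upper()
        entries.append((key, pos_ref, ca == cr and ca != "X"))
        mapped_keys.add(key)
    unmapped = [k for k in chain_seq.index.values() if k not in mapped_keys]
    if unmapped:
        logger.info(
            "chain %s: %d residue(s) not mapped to the reference",
            chain_seq.chain_id, len(unmapped),
        )
    return ResidueMap(chain_seq.chain_id, entries, aln.identity, unmapped)
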