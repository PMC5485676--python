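"""Optional star alignment of unaligned clone reads against a reference.

Clones of one amplicon are near-identical, so a full multiple alignment is
unnecessary: each clone is globally aligned to a reference clone with an
affine-gap Needleman-Wunsch (Gotoh), and reference-relative insertions are
propagated to all rows to form one shared column system.  This is an
explicit opt-in step; the analysis itself requires pre-aligned input.

Gap cost for a run of length k is ``gap_open + gap_extend * k``.  Traceback
ties are resolved deterministically, preferring match over deletion (gap in
the clone) over insertion (gap in the reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .errors import InputError
from .model import CloneAlignment, SampleRecord

NEG_INF = float("-inf")


@dataclass(frozen=True)
class AlignmentParams:
    match_score: float = 1.0
    mismatch_penalty: float = 1.0  # subtracted on mismatch
    gap_open: float = 4.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise InputError("gap penalties must be non-negative")
        if self.match_score <= -self.mismatch_penalty:
            raise InputError("match_score must exceed -mismatch_penalty")


def global_align(
    a: str, b: str, params: AlignmentParams = AlignmentParams()
) -> tuple[str, str, float]:
    """Optimal global alignment of `a` and `b`; returns (a_row, b_row, score)."""
    if not a or not b:
        raise InputError("cannot align an empty sequence")
    n, m = len(a), len(b)
    go, ge = params.gap_open, params.gap_extend
    sub = lambda x, y: params.match_score if x == y else -params.mismatch_penalty

    # M: a[i] aligned to b[j]; X: gap in b (consumes a); Y: gap in a (consumes b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(go + ge * i)
    for j in range(1, m + 1):
        Y[0][j] = -(go + ge * j)
    for i in range(1, n + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sub(ai, b[j - 1])
            Mi[j] = max(Mp[j - 1], Xp[j - 1], Yp[j - 1]) + s
            Xi[j] = max(Mp[j] - go - ge, Xp[j] - ge, Yp[j] - go - ge)
            Yi[j] = max(Mi[j - 1] - go - ge, Yi[j - 1] - ge, Xi[j - 1] - go - ge)

    eps = 1e-9
    i, j = n, m
    finals = (M[i][j], X[i][j], Y[i][j])
    score = max(finals)
    state = finals.index(score)  # 0=M, 1=X, 2=Y — preference order on ties
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        if j == 0:
            state = 1
        elif i == 0:
            state = 2
        if state == 0:
            s = sub(a[i - 1], b[j - 1])
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            prev = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            target = M[i][j] - s
            state = next(k for k in range(3) if abs(prev[k] - target) < eps)
            i, j = i - 1, j - 1
        elif state == 1:
            ra.append(a[i - 1])
            rb.append("-")
            if i == 1 and j == 0:
                i = 0
                continue
            cands = (M[i - 1][j] - go - ge, X[i - 1][j] - ge, Y[i - 1][j] - go - ge)
            state = next(k for k in range(3) if abs(cands[k] - X[i][j]) < eps)
            i -= 1
        else:
            ra.append("-")
            rb.append(b[j - 1])
            if j == 1 and i == 0:
                j = 0
                continue
            cands = (M[i][j - 1] - go - ge, X[i][j - 1] - go - ge, Y[i][j - 1] - ge)
            state = next(k for k in range(3) if abs(cands[k] - Y[i][j]) < eps)
            j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb)), score


def _segments(ra: str, rb: str) -> tuple[list[str], list[list[str]]]:
    """Split a pairwise alignment into per-reference-position pieces.

    Returns (aligned, segs) where aligned[k] is the clone character matched
    to reference position k, and segs[k] holds the clone characters inserted
    after consuming k reference characters (segs[0] = leading insertion).
    """
    segs: list[list[str]] = [[]]
    aligned: list[str] = []
    for x, y in zip(ra, rb):
        if x == "-":
            segs[-1].append(y)
        else:
            aligned.append(y)
            segs.append([])
    return aligned, segs


def align_to_reference(
    sequences: Mapping[str, str],
    reference: str | None = None,
    params: AlignmentParams = AlignmentParams(),
    samples: Mapping[str, SampleRecord] | None = None,
    gene_id: str = "",
) -> CloneAlignment:
    """Star-align clone sequences against one reference clone.

    `reference` names a clone in `sequences` (default: the first).  Each
    clone is pairwise-aligned to the reference; insertions relative to the
    reference are merged into shared columns by padding all other rows with
    gaps (insertions left-aligned within their padded block).  Removing
    gaps from any output row reproduces its input exactly.
    """
    ids = list(sequences)
    if len(ids) < 2:
        raise InputError("star alignment needs at least 2 sequences")
    for cid in ids:
        if not sequences[cid]:
            raise InputError(f"empty sequence for clone {cid!r}")
    ref_id = reference if reference is not None else ids[0]
    if ref_id not in sequences:
        raise InputError(f"reference {ref_id!r} not among the input sequences")
    ref = sequences[ref_id]
    rl = len(ref)

    pieces: dict[str, tuple[list[str], list[list[str]]]] = {
        ref_id: (list(ref), [[] for _ in range(rl + 1)])
    }
    for cid in ids:
        if cid == ref_id:
            continue
        ra, rb, _ = global_align(ref, sequences[cid], params)
        pieces[cid] = _segments(ra, rb)

    ins = [0] * (rl + 1)
    for aligned, segs in pieces.values():
        for k in range(rl + 1):
            ins[k] = max(ins[k], len(segs[k]))

    rows: dict[str, str] = {}
    for cid in ids:
        aligned, segs = pieces[cid]
        out: list[str] = []
        for k in range(rl + 1):
            seg = "".join(segs[k])
            out.append(seg + "-" * (ins[k] - len(seg)))
            if k < rl:
                out.append(aligned[k])
        rows[cid] = "".join(out)

    if samples is None:
        samples = {
            cid: SampleRecord(cid, isolate_id="NA", species_id="NA", gene_id=gene_id)
            for cid in ids
        }
    return CloneAlignment(
        gene_id=gene_id or next(iter(samples.values())).gene_id,
        clone_ids=tuple(ids),
        rows=rows,
        samples=dict(samples),
    )
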