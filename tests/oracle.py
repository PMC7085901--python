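"""Exhaustive all-offsets alignment oracle for verifying the seeded aligner.

Deliberately independent of the package's seed-and-extend implementation:
every offset of every reference is scanned with a vectorised Hamming
comparison (N never matches).  Shares only the *decision rules* (breakpoint
coverage, best-mismatch selection, ambiguity policy, per-fragment
deduplication) with the implementation, since those rules are the contract
under test for the aligner itself.
"""

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from spliceoform.gene_models import reverse_complement

_N = ord("N")


def _enc(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


class BruteRefs:
    def __init__(self, references: dict[str, str], read_length: int):
        self.windows = {}
        for name, seq in references.items():
            arr = _enc(seq)
            if len(arr) >= read_length:
                self.windows[name] = sliding_window_view(arr, read_length)


def brute_alignments(read: str, refs: BruteRefs, max_mismatches: int):
    """All full-read ungapped alignments on either strand, by exhaustive scan."""
    out = []
    for strand, oriented in (("+", read), ("-", reverse_complement(read))):
        q = _enc(oriented)
        for name, win in refs.windows.items():
            mm = ((win != q) | (win == _N) | (q == _N)).sum(axis=1)
            for off in np.nonzero(mm <= max_mismatches)[0]:
                out.append((name, int(off), strand, int(mm[off])))
    return out


def brute_matches_any(read: str, refs: BruteRefs, max_mismatches: int) -> bool:
    for strand, oriented in (("+", read), ("-", reverse_complement(read))):
        q = _enc(oriented)
        for win in refs.windows.values():
            mm = ((win != q) | (win == _N) | (q == _N)).sum(axis=1)
            if (mm <= max_mismatches).any():
                return True
    return False


def brute_junction_counts(reads, library, params):
    """Junction counts by exhaustive scan, mirroring the counting contract."""
    refs = BruteRefs(
        {f"{j.gene_id}|{j.upstream_exon}|{j.downstream_exon}": j.sequence
         for j in library},
        reads.read_length,
    )
    breakpoints = {
        f"{j.gene_id}|{j.upstream_exon}|{j.downstream_exon}": j.breakpoint_offset
        for j in library
    }
    key_of = {
        f"{j.gene_id}|{j.upstream_exon}|{j.downstream_exon}": j.key for j in library
    }
    counts = {j.key: 0 for j in library}
    seen = {j.key: set() for j in library}
    ambiguous = 0
    for rid, seq in zip(reads.ids, reads.sequences):
        best = {}
        for name, off, strand, mm in brute_alignments(seq, refs, params.max_mismatches):
            b = breakpoints[name]
            up_cov = b - off
            down_cov = off + len(seq) - b
            if up_cov >= params.min_overlap and down_cov >= params.min_overlap:
                if name not in best or mm < best[name]:
                    best[name] = mm
        if not best:
            continue
        best_mm = min(best.values())
        hits = [n for n, mm in best.items() if mm == best_mm]
        if len(hits) > 1 and params.ambiguous_policy == "discard":
            ambiguous += 1
            continue
        frag = rid.rsplit("/", 1)[0]
        for name in hits:
            key = key_of[name]
            if frag not in seen[key]:
                seen[key].add(frag)
                counts[key] += 1
    return counts, ambiguous
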