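"""Subgenome-of-origin read attribution.

A read is assigned to the donor subgenome only if it places on donor
transcripts within the mismatch budget (default 1, the strict one-base
rule), exactly one donor transcript attains the best placement, and no
recipient transcript accepts it within the budget; and symmetrically for
recipient reads.  Anything hit by both subgenomes, or tied within one, is
``ambiguous``; anything with no placement is ``unmapped``.

Candidate placements are found by exact k-mer seeding: with mismatch
budget 1 a read split into two non-overlapping seeds of length floor(L/2)
must have at least one exact seed at any true placement (pigeonhole), so
seed lookup followed by full Hamming verification at the implied offset is
exhaustive.  No indels are modeled and reads are matched forward-strand
only by default; ``both_strands=True`` adds reverse-complement lookup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ReadAttribution:
    """Classification of one read.

    ``best_hits`` lists every placement within the budget as
    ``(transcript_id, offset, mismatches)``.
    """

    read_id: str
    label: str  # donor | recipient | ambiguous | unmapped
    best_hits: tuple


class TranscriptIndex:
    """Exact k-mer seed table over a transcript set.

    Maps every k-mer occurrence to its (transcript, offset) posting; a
    lookup of any indexed k-mer returns all true occurrences.
    """

    def __init__(self, transcripts: dict[str, str], k: int):
        if k < 8:
            raise ValueError("k must be >= 8")
        self.k = int(k)
        self.transcripts = dict(transcripts)
        self._arrays = {}
        self._postings: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in self.transcripts.items():
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"transcript {tid!r} contains non-ACGT characters: {sorted(bad)}")
            self._arrays[tid] = np.frombuffer(seq.encode(), dtype="S1")
            for off in range(len(seq) - k + 1):
                self._postings.setdefault(seq[off:off + k], []).append((tid, off))

    def __len__(self) -> int:
        return sum(len(v) for v in self._postings.values())

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._postings.get(kmer, [])

    def array(self, tid: str) -> np.ndarray:
        return self._arrays[tid]


def build_index(transcripts: dict[str, str], k: int) -> TranscriptIndex:
    """Build the exact k-mer seed index (k >= 8, ACGT alphabet)."""
    return TranscriptIndex(transcripts, k)


def default_k(read_length: int) -> int:
    """Seed size guaranteeing a hit under 1 mismatch: floor(L/2), capped at 31."""
    return min(read_length // 2, 31)


def _placements(read_arr: np.ndarray, read: str, index: TranscriptIndex,
                max_mismatch: int) -> list[tuple[str, int, int]]:
    """All (transcript, offset, mismatches) placements within budget."""
    k = index.k
    L = len(read)
    seen: set[tuple[str, int]] = set()
    hits = []
    # non-overlapping seeds covering the read; budget+1 seeds suffice but
    # scanning every stride-k seed keeps the guarantee for any budget
    for s in range(0, L - k + 1, k):
        for tid, off in index.lookup(read[s:s + k]):
            start = off - s
            if start < 0:
                continue
            key = (tid, start)
            if key in seen:
                continue
            seen.add(key)
            tarr = index.array(tid)
            if start + L > len(tarr):
                continue
            mm = int((tarr[start:start + L] != read_arr).sum())
            if mm <= max_mismatch:
                hits.append((tid, start, mm))
    return hits


def _best(hits: list[tuple[str, int, int]]) -> tuple[int, set]:
    """Minimum mismatch count and the set of transcripts attaining it."""
    best = min(h[2] for h in hits)
    return best, {h[0] for h in hits if h[2] == best}


def attribute_read(read_id: str, read: str, recipient_index: TranscriptIndex,
                   donor_index: TranscriptIndex, max_mismatch: int = 1,
                   both_strands: bool = False) -> ReadAttribution:
    """Classify one read as donor / recipient / ambiguous / unmapped."""
    variants = [read]
    if both_strands:
        variants.append(revcomp(read))
    rec_hits: list = []
    don_hits: list = []
    for seq in variants:
        arr = np.frombuffer(seq.encode(), dtype="S1")
        rec_hits += _placements(arr, seq, recipient_index, max_mismatch)
        don_hits += _placements(arr, seq, donor_index, max_mismatch)
    all_hits = tuple(rec_hits + don_hits)
    if not all_hits:
        return ReadAttribution(read_id, "unmapped", ())
    if rec_hits and don_hits:
        return ReadAttribution(read_id, "ambiguous", all_hits)
    hits = don_hits or rec_hits
    _, best_tids = _best(hits)
    if len(best_tids) > 1:  # tied best within one subgenome: not unique
        return ReadAttribution(read_id, "ambiguous", all_hits)
    label = "donor" if don_hits else "recipient"
    return ReadAttribution(read_id, label, all_hits)


def attribute_reads(reads, recipient_index: TranscriptIndex,
                    donor_index: TranscriptIndex, max_mismatch: int = 1,
                    both_strands: bool = False):
    """Classify an iterable of (read_id, sequence) pairs.

    Returns ``(donor_counts, summary)``: per-donor-transcript counts of
    uniquely donor-attributed reads, and a summary dict partitioning every
    read exactly once over donor/recipient/ambiguous/unmapped.
    """
    counts = {tid: 0 for tid in donor_index.transcripts}
    summary = {"n_donor": 0, "n_recipient": 0, "n_ambiguous": 0, "n_unmapped": 0}
    for read_id, seq in reads:
        att = attribute_read(read_id, seq, recipient_index, donor_index,
                             max_mismatch, both_strands)
        summary[f"n_{att.label}"] += 1
        if att.label == "donor":
            best, tids = _best(list(att.best_hits))
            counts[next(iter(tids))] += 1
    return counts, summary


def read_fastq(path):
    """Yield (read_id, sequence) from a Phred+33 FASTQ file."""
    with open(path) as fh:
        n = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            n += 1
            if not (header.startswith("@") and plus.startswith("+") and qual):
                raise ValueError(f"truncated or malformed FASTQ record {n}")
            yield header[1:].strip().split()[0], seq.strip()


def brute_force_attribute(read_id: str, read: str,
                          recipient: dict[str, str], donor: dict[str, str],
                          max_mismatch: int = 1) -> ReadAttribution:
    """Exhaustive Hamming oracle: scan every offset of every transcript.

    Semantics identical to :func:`attribute_read`; used as the independent
    reference in tests, never in the pipeline.
    """
    arr = np.frombuffer(read.encode(), dtype="S1")
    L = len(read)

    def scan(transcripts):
        hits = []
        for tid, seq in transcripts.items():
            tarr = np.frombuffer(seq.encode(), dtype="S1")
            if len(tarr) < L:
                continue
            win = np.lib.stride_tricks.sliding_window_view(tarr, L)
            mm = (win != arr).sum(axis=1)
            for off in np.flatnonzero(mm <= max_mismatch):
                hits.append((tid, int(off), int(mm[off])))
        return hits

    rec_hits, don_hits = scan(recipient), scan(donor)
    all_hits = tuple(rec_hits + don_hits)
    if not all_hits:
        return ReadAttribution(read_id, "unmapped", ())
    if rec_hits and don_hits:
        return ReadAttribution(read_id, "ambiguous", all_hits)
    hits = don_hits or rec_hits
    _, best_tids = _best(hits)
    if len(best_tids) > 1:
        return ReadAttribution(read_id, "ambiguous", all_hits)
    return ReadAttribution(read_id, "donor" if don_hits else "recipient", all_hits)
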