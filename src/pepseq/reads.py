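"""Paired-read processing: demultiplexing, filtering, allele classification.

Read 1 identifies the library member by exact matching of its first eight
nucleotides against the designed prefixes (no error tolerance — a single
mismatch in the prefix leaves the read unassigned). Read 2 covers the
target site and is aligned globally to the reference amplicon, then passed
through three quality rules before classification:

* reads with mean PHRED quality below 30 are dropped;
* mismatches at bases with PHRED quality below 30 are masked (treated as
  reference);
* indels lacking at least three flanking matched nucleotides with PHRED
  quality ≥ 30 on both sides are masked (the allele is evaluated as if the
  indel were absent).

A kept read is then classified into exactly one of {prime_edited, unedited,
indel, other} by reconstructing the read's effective sequence (after
masking) and comparing it against the fully edited and the reference
amplicon; partial edits fall into ``other``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from pepseq.align import Alignment, AlnEvent, align_target, gapless_alignment
from pepseq.edits import EditSpec
from pepseq.library import PREFIX_LEN, LibraryDesignError, PeptideRecord

__all__ = [
    "PeptideDemuxer",
    "demux_peptide",
    "MaskedAlignment",
    "OutcomeCall",
    "CountMatrix",
    "phred_array",
    "filter_read",
    "classify_outcome",
    "count_outcomes",
    "read_sample_sheet",
]

CATEGORIES = ("prime_edited", "unedited", "indel", "other")

MIN_MEAN_Q = 30.0
MIN_BASE_Q = 30
MIN_FLANK_MATCHES = 3

# gap-free fast path is provably optimal up to this many mismatches under
# the default scoring (see align.gapless_alignment)
_FASTPATH_MAX_MISMATCHES = 5


class PeptideDemuxer:
    """Exact 8-nt prefix lookup from read 1 to peptide identity."""

    def __init__(self, library: Sequence[PeptideRecord], prefix_len: int = PREFIX_LEN):
        self.prefix_len = prefix_len
        self._table: dict[str, str] = {}
        for rec in library:
            if rec.nt_seq is None:
                raise LibraryDesignError(f"{rec.peptide_id} has no nucleotide encoding")
            prefix = rec.nt_seq[:prefix_len]
            if prefix in self._table:
                raise LibraryDesignError(
                    f"duplicate {prefix_len}-nt prefix {prefix}: "
                    f"{self._table[prefix]} vs {rec.peptide_id}"
                )
            self._table[prefix] = rec.peptide_id

    def __call__(self, read1_seq: str) -> Optional[str]:
        """Peptide id for a read-1 sequence, or None if unassigned."""
        if len(read1_seq) < self.prefix_len:
            return None
        return self._table.get(read1_seq[: self.prefix_len])

    def __len__(self) -> int:
        return len(self._table)


def demux_peptide(read1_seq: str, library: Sequence[PeptideRecord]) -> Optional[str]:
    """One-shot exact-prefix demultiplexing of a single read-1 sequence.

    Builds the prefix table on every call; streaming callers should hold a
    :class:`PeptideDemuxer` instead.
    """
    return PeptideDemuxer(library)(read1_seq)


@dataclass
class MaskedAlignment:
    """An alignment with low-confidence events masked out."""

    alignment: Alignment
    unmasked_mismatches: list[AlnEvent]
    unmasked_indels: list[AlnEvent]
    masked_mismatches: list[AlnEvent] = field(default_factory=list)
    masked_indels: list[AlnEvent] = field(default_factory=list)

    def effective_seq(self) -> str:
        """The read projected onto the reference after masking.

        Masked mismatches contribute the reference base, masked deletions
        restore the deleted reference bases, and masked insertions are
        dropped, so the effective sequence is what the read claims about
        the amplicon at high confidence.
        """
        masked = set(map(id, self.masked_mismatches)) | set(map(id, self.masked_indels))
        aln = self.alignment
        query = aln.query
        ref = aln.ref
        parts: list[str] = []
        for ev in aln.events:
            if id(ev) in masked:
                parts.append(ref[ev.ref_start : ev.ref_end])
            elif ev.kind == "deletion":
                pass
            elif ev.kind == "insertion" or ev.kind == "mismatch":
                parts.append(query[ev.q_start : ev.q_end])
            else:
                parts.append(ref[ev.ref_start : ev.ref_end])
        return "".join(parts)


@dataclass(frozen=True)
class OutcomeCall:
    """Final per-read call: allele category plus read disposition."""

    category: Optional[str]  # one of CATEGORIES, None if not kept
    disposition: str  # kept | dropped_low_quality | unassigned_peptide


def phred_array(quality_string: str) -> np.ndarray:
    """PHRED scores from a Sanger/Illumina-1.8 (+33 offset) quality string."""
    return np.frombuffer(quality_string.encode("ascii"), dtype=np.uint8).astype(np.int32) - 33


def filter_read(
    aln: Alignment,
    qualities: np.ndarray,
    min_mean_q: float = MIN_MEAN_Q,
    min_base_q: int = MIN_BASE_Q,
    min_flank_matches: int = MIN_FLANK_MATCHES,
) -> tuple[str, Optional[MaskedAlignment]]:
    """Apply the mean-quality drop rule and per-event masking rules.

    Returns ``("dropped_low_quality", None)`` when the read's mean PHRED
    quality is below ``min_mean_q``; otherwise ``("kept", masked)`` where
    mismatches at bases below ``min_base_q`` and indels without
    ``min_flank_matches`` adjacent high-quality matched columns on both
    sides have been masked.
    """
    qualities = np.asarray(qualities)
    if len(qualities) != len(aln.query):
        raise ValueError(
            f"quality length {len(qualities)} != read length {len(aln.query)}"
        )
    if qualities.mean() < min_mean_q:
        return "dropped_low_quality", None

    events = aln.events
    unmasked_mm: list[AlnEvent] = []
    masked_mm: list[AlnEvent] = []
    unmasked_indel: list[AlnEvent] = []
    masked_indel: list[AlnEvent] = []
    for idx, ev in enumerate(events):
        if ev.kind == "mismatch":
            if qualities[ev.q_start] < min_base_q:
                masked_mm.append(ev)
            else:
                unmasked_mm.append(ev)
        elif ev.kind in ("insertion", "deletion"):
            if _indel_has_flanks(events, idx, qualities, min_base_q, min_flank_matches):
                unmasked_indel.append(ev)
            else:
                masked_indel.append(ev)
    return "kept", MaskedAlignment(aln, unmasked_mm, unmasked_indel, masked_mm, masked_indel)


def _indel_has_flanks(
    events: Sequence[AlnEvent],
    idx: int,
    qualities: np.ndarray,
    min_base_q: int,
    k: int,
) -> bool:
    """True if the indel is flanked by >= k high-quality matched columns on each side."""
    def good(ev: AlnEvent) -> bool:
        return ev.kind == "match" and qualities[ev.q_start] >= min_base_q

    left = events[max(0, idx - k) : idx]
    right = events[idx + 1 : idx + 1 + k]
    if len(left) < k or len(right) < k:
        return False
    return all(good(ev) for ev in left) and all(good(ev) for ev in right)


def classify_outcome(masked: MaskedAlignment, spec: EditSpec) -> OutcomeCall:
    """Assign a kept read to one allele category.

    Precedence: a read whose effective sequence equals the fully edited
    amplicon is ``prime_edited``; otherwise any unmasked indel makes it
    ``indel``; otherwise zero unmasked differences make it ``unedited``;
    everything else — including reads carrying only part of the programmed
    edit — is ``other``. Edit calling is all-or-nothing.
    """
    eff = masked.effective_seq()
    if eff == spec.edited_amplicon:
        return OutcomeCall("prime_edited", "kept")
    if masked.unmasked_indels:
        return OutcomeCall("indel", "kept")
    if eff == spec.ref_amplicon:
        return OutcomeCall("unedited", "kept")
    if not masked.unmasked_mismatches:
        # differs from reference only through masked events
        return OutcomeCall("unedited", "kept")
    return OutcomeCall("other", "kept")


# ---------------------------------------------------------------------------
# streaming counters


@dataclass
class CountMatrix:
    """Per-peptide, per-replicate outcome counts.

    ``df`` is tidy with one row per (peptide_id, replicate) and columns
    ``n`` (kept reads) plus the four allele categories; ``n`` always equals
    the category sum. ``tallies`` records reads that never reached
    classification (unassigned peptide prefix, low mean quality).
    """

    df: pd.DataFrame
    tallies: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = {"peptide_id", "replicate", "n", *CATEGORIES}
        missing = expected - set(self.df.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        cat_sum = self.df[list(CATEGORIES)].sum(axis=1)
        if not (self.df["n"] == cat_sum).all():
            raise ValueError("category counts do not sum to n")

    @property
    def replicates(self) -> list[str]:
        return sorted(self.df["replicate"].unique())

    @property
    def peptides(self) -> list[str]:
        return sorted(self.df["peptide_id"].unique())

    def pivot(self, column: str) -> pd.DataFrame:
        """Peptides x replicates matrix of one column (e.g. 'n', 'prime_edited')."""
        return self.df.pivot(index="peptide_id", columns="replicate", values=column).fillna(0)

    def edited_fraction(self) -> pd.DataFrame:
        n = self.pivot("n")
        y = self.pivot("prime_edited")
        return y / n.where(n > 0)

    def subset(self, peptide_ids: Iterable[str]) -> "CountMatrix":
        keep = self.df["peptide_id"].isin(set(peptide_ids))
        return CountMatrix(self.df.loc[keep].reset_index(drop=True), self.tallies)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        return cls(pd.read_csv(path, sep="\t"))


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV with columns replicate, r1, r2 [, revcomp_r2]."""
    sheet = pd.read_csv(path, sep="\t")
    required = {"replicate", "r1", "r2"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def _open_maybe_gzip(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_read_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[tuple]:
    """Yield ((seq1, qual1), (seq2, qual2)) tuples from paired FASTQ files."""
    with _open_maybe_gzip(r1_path) as fh1, _open_maybe_gzip(r2_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2, strict=True):
            yield (s1, q1), (s2, q2)


def _align_read(seq: str, ref: str) -> Alignment:
    if len(seq) == len(ref):
        h = sum(1 for a, b in zip(seq, ref) if a != b)
        if h <= _FASTPATH_MAX_MISMATCHES:
            return gapless_alignment(seq, ref)
    return align_target(seq, ref)


def count_outcomes(
    sample_sheet: pd.DataFrame,
    library: Sequence[PeptideRecord],
    spec: EditSpec,
    replicates: Optional[Sequence[str]] = None,
    min_mean_q: float = MIN_MEAN_Q,
    min_base_q: int = MIN_BASE_Q,
    cache_size: int = 200_000,
) -> CountMatrix:
    """Stream paired FASTQ files into a per-peptide outcome count matrix.

    Every library peptide appears in the output for every replicate in the
    sheet, with zero counts where no read was seen. Reads whose first eight
    nucleotides match no designed prefix are tallied as unassigned; reads
    failing the mean-quality rule as dropped. Classification results are
    memoised on (sequence, quality) pairs, which collapses the bulk of
    deeply-sequenced amplicon data onto a handful of alignments.
    """
    demux = PeptideDemuxer(library)
    pid_list = [rec.peptide_id for rec in library]
    if replicates is not None:
        unknown = set(sample_sheet["replicate"]) - set(replicates)
        if unknown:
            raise ValueError(f"unknown replicate labels in sample sheet: {sorted(unknown)}")
    rep_list = list(dict.fromkeys(sample_sheet["replicate"]))

    counts: dict[tuple[str, str], np.ndarray] = {
        (pid, rep): np.zeros(len(CATEGORIES), dtype=np.int64)
        for pid in pid_list
        for rep in rep_list
    }
    tallies = {
        rep: {"total": 0, "kept": 0, "dropped_low_quality": 0, "unassigned_peptide": 0}
        for rep in rep_list
    }
    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    cache: dict[tuple[str, str], tuple[str, Optional[str]]] = {}

    for row in sample_sheet.itertuples(index=False):
        rep = row.replicate
        revcomp = bool(getattr(row, "revcomp_r2", False))
        tally = tallies[rep]
        for (s1, _q1), (s2, q2) in iter_read_pairs(row.r1, row.r2):
            tally["total"] += 1
            pid = demux(s1)
            if pid is None:
                tally["unassigned_peptide"] += 1
                continue
            if revcomp:
                s2 = reverse_complement(s2)
                q2 = q2[::-1]
            key = (s2, q2)
            hit = cache.get(key)
            if hit is None:
                quals = phred_array(q2)
                aln = _align_read(s2, spec.ref_amplicon)
                disposition, masked = filter_read(
                    aln, quals, min_mean_q=min_mean_q, min_base_q=min_base_q
                )
                if disposition == "kept":
                    hit = (disposition, classify_outcome(masked, spec).category)
                else:
                    hit = (disposition, None)
                if len(cache) < cache_size:
                    cache[key] = hit
            disposition, category = hit
            if disposition != "kept":
                tally["dropped_low_quality"] += 1
                continue
            tally["kept"] += 1
            counts[(pid, rep)][cat_index[category]] += 1

    rows = []
    for (pid, rep), vec in counts.items():
        rows.append(
            {
                "peptide_id": pid,
                "replicate": rep,
                "n": int(vec.sum()),
                **{cat: int(vec[i]) for cat, i in cat_index.items()},
            }
        )
    return CountMatrix(pd.DataFrame(rows), tallies)
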