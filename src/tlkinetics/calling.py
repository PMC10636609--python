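"""T-to-C mutation calling from aligned reads.

Converts aligned-read evidence into per-read retained mutation counts
(tc). A candidate T-to-C event survives only if its base quality is at
least 40, it sits at least 3 nt from both read ends, and its site is
not a known SNP or alignment artifact. SNP sites are detected from the
unlabeled (-s4U) control libraries: a site whose control mutation count
is binomially improbable under the background error rate (one-sided
p < 0.05) is masked. Uniquely mapped proper pairs are selected by their
SAM flag pair (83/163 or 99/147).

Events are expressed in transcriptional orientation throughout: a
genomic A>G mismatch in a read from a minus-strand gene is a T-to-C
event on the transcript (the labeling chemistry acts on transcript
uridines).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "MutationEvent", "ReadRecord", "SnpMask", "CallStats",
    "select_proper_pairs", "filter_mutations", "identify_snp_sites",
    "count_mutations", "parse_sam",
]

ALLOWED_FLAG_PAIRS = (frozenset({83, 163}), frozenset({99, 147}))
DEFAULT_MIN_QUALITY = 40
DEFAULT_END_EXCLUSION = 3
DEFAULT_SNP_ALPHA = 0.05


@dataclass(frozen=True)
class MutationEvent:
    """One candidate mismatch on a read, in transcript orientation."""

    ref_pos: int          # 0-based genomic coordinate
    base_quality: int     # phred
    offset_from_5p: int
    offset_from_3p: int
    ref_base: str = "T"
    alt_base: str = "C"


@dataclass
class ReadRecord:
    """One aligned read's gene assignment and candidate mutation events."""

    sample_id: str
    gene_id: str
    read_id: str
    mate_flags: tuple[int, int] = (99, 147)
    events: list[MutationEvent] = field(default_factory=list)
    n_t_sites: int = 0


@dataclass
class CallStats:
    """Attrition counters accumulated across calling operations."""

    pairs_in: int = 0
    pairs_dropped_flags: int = 0
    records_malformed: int = 0
    reads_missing_md: int = 0
    reads_no_gene: int = 0
    events_dropped: Counter = field(default_factory=Counter)

    def as_dict(self):
        d = {k: getattr(self, k) for k in
             ("pairs_in", "pairs_dropped_flags", "records_malformed",
              "reads_missing_md", "reads_no_gene")}
        d["events_dropped"] = dict(self.events_dropped)
        return d


class SnpMask:
    """Masked (gene, position) sites excluded from mutation counting.

    Holds the per-site control evidence (mutation count, coverage,
    binomial p-value) for sites detected from controls, and any sites
    merged from an external variant blacklist.
    """

    def __init__(self, sites=(), site_table: pd.DataFrame | None = None):
        self._sites = set(sites)
        self.site_table = site_table

    def __contains__(self, key):
        return tuple(key) in self._sites

    def __len__(self):
        return len(self._sites)

    def __iter__(self):
        return iter(self._sites)

    @property
    def sites(self):
        return frozenset(self._sites)

    def merge_blacklist(self, sites: Iterable[tuple]) -> "SnpMask":
        """Add externally called variant sites (e.g. a bcftools list)."""
        self._sites.update(tuple(s) for s in sites)
        return self

    @classmethod
    def from_tsv(cls, path):
        """Load a site blacklist TSV with columns gene_id, ref_pos."""
        t = pd.read_csv(path, sep="\t")
        return cls(zip(t["gene_id"], t["ref_pos"].astype(int)))


def select_proper_pairs(records: Iterable[ReadRecord],
                        stats: CallStats | None = None
                        ) -> Iterator[ReadRecord]:
    """Keep only reads whose (flag, mate flag) pair is 83/163 or 99/147.

    Uniquely mapped, properly paired reads carry exactly these flag
    combinations; everything else (unmapped mates, secondary/duplicate
    alignments, odd orientations) is dropped and counted in ``stats``.
    """
    stats = stats if stats is not None else CallStats()
    for rec in records:
        stats.pairs_in += 1
        try:
            pair = frozenset(int(f) for f in rec.mate_flags)
        except (TypeError, ValueError):
            stats.records_malformed += 1
            continue
        if pair in ALLOWED_FLAG_PAIRS:
            yield rec
        else:
            stats.pairs_dropped_flags += 1


def filter_mutations(record: ReadRecord,
                     min_quality: int = DEFAULT_MIN_QUALITY,
                     end_exclusion_nt: int = DEFAULT_END_EXCLUSION,
                     snp_mask: SnpMask | None = None,
                     stats: CallStats | None = None) -> int:
    """Count the T-to-C events on a read that survive all filters.

    An event is retained iff it is a T>C mismatch (transcript
    orientation), its base quality is >= ``min_quality``, it lies at
    least ``end_exclusion_nt`` nucleotides from both read ends (offsets
    0..end_exclusion_nt-1 are excluded), and its site is not masked.
    """
    tc = 0
    for ev in record.events:
        if ev.offset_from_5p < 0 or ev.offset_from_3p < 0:
            raise ValueError(
                f"negative read-end offset on read {record.read_id!r}")
        if not (ev.ref_base == "T" and ev.alt_base == "C"):
            reason = "not_t_to_c"
        elif ev.base_quality < min_quality:
            reason = "low_quality"
        elif min(ev.offset_from_5p, ev.offset_from_3p) < end_exclusion_nt:
            reason = "read_end"
        elif snp_mask is not None and (record.gene_id, ev.ref_pos) in snp_mask:
            reason = "snp_masked"
        else:
            tc += 1
            continue
        if stats is not None:
            stats.events_dropped[reason] += 1
    return tc


def identify_snp_sites(control_sites: pd.DataFrame,
                       background_rate: float | None = None,
                       alpha: float = DEFAULT_SNP_ALPHA,
                       max_iter: int = 5) -> SnpMask:
    """Mask sites with implausibly many mutations in unlabeled controls.

    ``control_sites`` has one row per (gene_id, ref_pos) with columns
    ``mutations`` (mutated control reads) and ``coverage``. A site is
    masked when the one-sided binomial tail
    ``P(X >= mutations | coverage, background_rate)`` is below
    ``alpha``. When ``background_rate`` is not supplied it is estimated
    as the pooled control mutation fraction over unmasked sites,
    re-estimated after masking until the mask is stable (genuine SNPs
    would otherwise inflate the background estimate).
    """
    req = {"gene_id", "ref_pos", "mutations", "coverage"}
    if not req <= set(control_sites.columns):
        raise ValueError(f"control site table needs columns {sorted(req)}")
    if (control_sites["coverage"] < 1).any():
        raise ValueError("every site needs control coverage >= 1")
    if background_rate is not None and not 0 < background_rate < 1:
        raise ValueError("background_rate must lie in (0, 1)")

    muts = control_sites["mutations"].to_numpy()
    cov = control_sites["coverage"].to_numpy()
    estimate_bg = background_rate is None
    masked = np.zeros(len(control_sites), dtype=bool)
    for _ in range(max_iter):
        if estimate_bg:
            keep = ~masked
            tot = cov[keep].sum()
            background_rate = float(muts[keep].sum() / tot) if tot else 0.0
            background_rate = min(max(background_rate, 1e-9), 1 - 1e-9)
        # P(X >= k) = sf(k - 1)
        pvals = binom.sf(muts - 1, cov, background_rate)
        new_masked = pvals < alpha
        if np.array_equal(new_masked, masked):
            masked = new_masked
            break
        masked = new_masked
        if not estimate_bg:
            break

    table = control_sites.copy()
    table["p_value"] = pvals
    table["masked"] = masked
    table["background_rate"] = background_rate
    sites = set(zip(table.loc[masked, "gene_id"],
                    table.loc[masked, "ref_pos"].astype(int)))
    return SnpMask(sites, table)


def count_mutations(records: Iterable[ReadRecord],
                    snp_mask: SnpMask | None,
                    sample_meta: dict,
                    min_quality: int = DEFAULT_MIN_QUALITY,
                    end_exclusion_nt: int = DEFAULT_END_EXCLUSION,
                    genes: set | None = None,
                    stats: CallStats | None = None) -> pd.DataFrame:
    """Apply the mutation filters over a read stream.

    ``sample_meta`` maps sample_id -> (condition, s4u indicator).
    Returns a MutationCountTable DataFrame with one row per retained
    read — reads whose every event fails the filters stay as tc=0 rows,
    since a mutation-free read is still an observation. Reads assigned
    to genes outside ``genes`` (when given) are dropped and counted.
    """
    stats = stats if stats is not None else CallStats()
    rows = []
    for rec in records:
        if genes is not None and rec.gene_id not in genes:
            stats.reads_no_gene += 1
            continue
        cond, s4u = sample_meta[rec.sample_id]
        tc = filter_mutations(rec, min_quality, end_exclusion_nt,
                              snp_mask, stats)
        rows.append((rec.sample_id, cond, int(s4u), rec.gene_id,
                     rec.read_id, tc))
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "s4u", "gene_id",
                       "read_id", "tc"])


# ---------------------------------------------------------------------------
# SAM parsing

def _load_annotation(annotation):
    """Gene intervals -> per-chromosome interval tree of (gene_id, strand).

    Accepts a BED path (0-based half-open; optional name/strand columns)
    or a DataFrame with columns chrom, start, end, gene_id, strand.
    """
    from intervaltree import IntervalTree

    if isinstance(annotation, (str,)) or hasattr(annotation, "__fspath__"):
        df = pd.read_csv(
            annotation, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene_id", "score", "strand"],
            usecols=range(6))
    else:
        df = annotation
    trees: dict = defaultdict(IntervalTree)
    for row in df.itertuples(index=False):
        strand = getattr(row, "strand", "+") or "+"
        trees[row.chrom].addi(int(row.start), int(row.end),
                              (row.gene_id, strand))
    return trees


def parse_sam(path, annotation, sample_id: str = "",
              stats: CallStats | None = None) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a SAM/BAM file with MD tags.

    Mismatches are reconstructed from the MD tag via pysam's aligned
    pairs; only T>C mismatches in transcript orientation (plus-strand
    gene: genomic T>C; minus-strand gene: genomic A>G) become events.
    ``n_t_sites`` counts covered reference positions that are T on the
    transcript strand. Reads overlapping no annotated gene are dropped;
    reads lacking an MD tag are skipped with a warning count. Mate
    flags are paired up by query name, so a read's record carries
    (own flag, mate flag).
    """
    import pysam

    stats = stats if stats is not None else CallStats()
    trees = _load_annotation(annotation)
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        alns = [a for a in fh if not a.is_unmapped]
    flags_by_name = defaultdict(list)
    for a in alns:
        flags_by_name[a.query_name].append(a.flag)

    for a in alns:
        if not a.has_tag("MD"):
            stats.reads_missing_md += 1
            continue
        tree = trees.get(a.reference_name)
        hits = tree.overlap(a.reference_start, a.reference_end) if tree else ()
        if not hits:
            stats.reads_no_gene += 1
            continue
        gene_id, strand = sorted(hits)[0].data
        own = a.flag
        mates = [f for f in flags_by_name[a.query_name] if f != own]
        mate = mates[0] if mates else 0

        want_ref, want_alt = ("T", "C") if strand == "+" else ("A", "G")
        L = a.query_length or len(a.query_sequence or "")
        quals = a.query_qualities
        seq = a.query_sequence or ""
        events = []
        n_t = 0
        for qpos, rpos, ref in a.get_aligned_pairs(matches_only=True,
                                                   with_seq=True):
            ref_up = ref.upper()
            if ref_up == want_ref:
                n_t += 1
            if ref.islower() and ref_up == want_ref \
                    and seq[qpos].upper() == want_alt:
                off5 = qpos if not a.is_reverse else L - 1 - qpos
                events.append(MutationEvent(
                    ref_pos=rpos,
                    base_quality=int(quals[qpos]) if quals is not None else 0,
                    offset_from_5p=off5,
                    offset_from_3p=L - 1 - off5,
                    ref_base="T", alt_base="C"))
        yield ReadRecord(sample_id=sample_id, gene_id=gene_id,
                         read_id=a.query_name, mate_flags=(own, mate),
                         events=events, n_t_sites=n_t)
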