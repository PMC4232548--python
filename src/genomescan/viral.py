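"""Retroviral integration-site detection from scaffolds and read pairs.

Two independent evidence paths, mirroring how proviral insertions are
found in a transformed genome:

* de novo assembly scaffolds carrying both host and viral sequence
  ("mixed" scaffolds) localize the junction through their host-side
  alignment; and
* read pairs with one fully viral mate cluster their host-mapped mates
  near the junction.

Alignments are consumed in 12-column tabular form (BLAST outfmt-6 column
order).  For synthetic data an exact k-mer matcher produces equivalent
hits, so no external aligner is needed at test scale.  Zygosity of a
junction follows from spanning reads: an insertion carried by every
allele leaves no read pair spanning the uninserted site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import revcomp

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

VIRAL_ONLY = "viral_only"
HOST_ONLY = "host_only"
MIXED = "mixed"

ALL_ALLELES = "all_alleles"
PARTIAL = "partial"
NO_CALL = "no_call"

DEFAULT_MIN_HIT_LEN = 200
DEFAULT_MIN_IDENTITY = 90.0
DEFAULT_CLUSTER_WINDOW = 1000
DEFAULT_MIN_SUPPORT = 3
DEFAULT_MAX_JUNCTION_GAP = 50


@dataclass(frozen=True)
class AlignmentHit:
    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int  # 1-based inclusive, qstart <= qend always
    qend: int
    sstart: int  # sstart > send on the minus strand
    send: int
    evalue: float = 0.0
    bitscore: float = 0.0

    @property
    def subject_strand(self) -> str:
        return "+" if self.sstart <= self.send else "-"


@dataclass
class IntegrationSite:
    chrom: str
    pos: int  # 1-based junction coordinate on the host genome
    orientation: str  # forward / reverse / unknown (viral vs host strand)
    evidence: str  # mixed_scaffold / read_pairs / both
    support: int
    zygosity: str = NO_CALL
    resolved: bool = True
    scaffold: str = ""


@dataclass
class ScaffoldCall:
    scaffold: str
    category: str
    excluded_short_viral: bool = False  # sole viral evidence was sub-threshold
    zero_evidence: bool = False
    viral_hits: list = field(default_factory=list)
    host_hits: list = field(default_factory=list)


def read_hits_tsv(path) -> list[AlignmentHit]:
    df = pd.read_csv(path, sep="\t", comment="#", names=OUTFMT6_COLUMNS)
    return [AlignmentHit(**row) for row in df.to_dict("records")]


def write_hits_tsv(hits: Sequence[AlignmentHit], path) -> None:
    pd.DataFrame([h.__dict__ for h in hits])[OUTFMT6_COLUMNS].to_csv(
        path, sep="\t", header=False, index=False
    )


def exact_hits(queries: Mapping[str, str], subjects: Mapping[str, str],
               k: int = 31, min_len: int = 50) -> list[AlignmentHit]:
    """Maximal exact-match alignments between queries and subjects.

    Seeds shared k-mers, chains seeds on the same diagonal into maximal
    runs, and reports runs of at least ``min_len`` bases in outfmt-6
    convention (100% identity; minus-strand hits have sstart > send).
    Queries are indexed so each subject is scanned once.
    """
    index: dict[str, list[tuple[str, str, int]]] = {}
    qlen: dict[str, int] = {}
    for qid, seq in queries.items():
        seq = seq.upper()
        qlen[qid] = len(seq)
        for orient, s in (("+", seq), ("-", revcomp(seq))):
            for i in range(len(s) - k + 1):
                index.setdefault(s[i:i + k], []).append((qid, orient, i))
    hits: list[AlignmentHit] = []
    for sid, sseq in subjects.items():
        sseq = sseq.upper()
        matches: dict[tuple[str, str, int], list[int]] = {}
        for spos in range(len(sseq) - k + 1):
            for qid, orient, qpos in index.get(sseq[spos:spos + k], ()):
                matches.setdefault((qid, orient, spos - qpos), []).append(spos)
        for (qid, orient, diag), sposs in matches.items():
            sposs.sort()
            run_start = prev = sposs[0]
            runs = []
            for p in sposs[1:]:
                if p != prev + 1:
                    runs.append((run_start, prev))
                    run_start = p
                prev = p
            runs.append((run_start, prev))
            for s0, s1 in runs:
                m = s1 - s0 + k  # exact match length
                if m < min_len:
                    continue
                q0 = s0 - diag  # 0-based start in (oriented) query
                if orient == "+":
                    qstart, qend = q0 + 1, q0 + m
                    sstart, send = s0 + 1, s0 + m
                else:
                    n = qlen[qid]
                    qstart, qend = n - (q0 + m) + 1, n - q0
                    sstart, send = s0 + m, s0 + 1
                hits.append(
                    AlignmentHit(qid, sid, 100.0, m, 0, 0,
                                 qstart, qend, sstart, send, 0.0, 2.0 * m)
                )
    return hits


def classify_scaffold(viral_hits: Sequence[AlignmentHit],
                      host_hits: Sequence[AlignmentHit],
                      scaffold_length: int,
                      min_hit_len: int = DEFAULT_MIN_HIT_LEN,
                      min_identity: float = DEFAULT_MIN_IDENTITY) -> ScaffoldCall:
    """Categorize one scaffold from its surviving viral and host hits.

    Hits shorter than ``min_hit_len`` or below ``min_identity`` percent
    identity are discarded before categorization; a scaffold whose only
    viral evidence was discarded keeps an excluded-short annotation (the
    short-phage-match exclusion), and a scaffold with no hits at all is
    host_only with a zero-evidence flag.
    """
    name = (viral_hits[0].qseqid if viral_hits else
            host_hits[0].qseqid if host_hits else "")
    keep = lambda h: h.length >= min_hit_len and h.pident >= min_identity
    v_keep = [h for h in viral_hits if keep(h)]
    h_keep = [h for h in host_hits if keep(h)]
    excluded_short = bool(viral_hits) and not v_keep
    if not viral_hits and not host_hits:
        return ScaffoldCall(name, HOST_ONLY, zero_evidence=True)
    if v_keep and h_keep:
        cat = MIXED
    elif v_keep:
        cat = VIRAL_ONLY
    else:
        cat = HOST_ONLY
    return ScaffoldCall(name, cat, excluded_short_viral=excluded_short,
                        viral_hits=v_keep, host_hits=h_keep)


def locate_integration(call: ScaffoldCall,
                       max_gap: int = DEFAULT_MAX_JUNCTION_GAP) -> IntegrationSite:
    """Derive the host junction coordinate from a mixed scaffold.

    The host and viral alignments must be adjacent on the scaffold (gap
    at most ``max_gap`` unexplained bases); the junction is the host
    genomic coordinate at the scaffold position where the host alignment
    meets the viral sequence, and the orientation compares viral and
    host subject strands.  Non-adjacent segments yield an unresolved
    candidate.
    """
    if call.category != MIXED:
        raise ValueError("integration can only be located on a mixed scaffold")
    best = None
    for h in call.host_hits:
        for v in call.viral_hits:
            if h.qend <= v.qstart:  # host segment left of viral segment
                gap = v.qstart - h.qend - 1
                junction = h.send if h.subject_strand == "+" else h.send
            elif v.qend <= h.qstart:  # viral left of host
                gap = h.qstart - v.qend - 1
                junction = h.sstart
            else:  # overlapping alignments: junction at the host edge
                gap = 0
                junction = h.send if h.qstart < v.qstart else h.sstart
            orientation = "forward" if h.subject_strand == v.subject_strand else "reverse"
            cand = (gap, junction, h.sseqid, orientation)
            if best is None or cand[0] < best[0]:
                best = cand
    gap, junction, chrom, orientation = best
    return IntegrationSite(
        chrom=chrom, pos=int(junction), orientation=orientation,
        evidence="mixed_scaffold", support=1,
        resolved=gap <= max_gap, scaffold=call.scaffold,
    )


def viral_kmer_index(viral_seqs: Mapping[str, str] | str, k: int = 25) -> frozenset:
    """Set of viral k-mers (both strands) for mate-membership queries."""
    if isinstance(viral_seqs, str):
        viral_seqs = {"virus": viral_seqs}
    kmers = set()
    for seq in viral_seqs.values():
        for s in (seq.upper(), revcomp(seq.upper())):
            for i in range(len(s) - k + 1):
                kmers.add(s[i:i + k])
    return frozenset(kmers)


def is_viral_read(seq: str, viral_kmers: frozenset, k: int = 25,
                  min_fraction: float = 0.8) -> bool:
    seq = seq.upper()
    n = len(seq) - k + 1
    if n <= 0:
        return False
    hits = sum(1 for i in range(n) if seq[i:i + k] in viral_kmers)
    return hits / n >= min_fraction


def place_read(seq: str, host_sequences: Mapping[str, str]) -> tuple[str, int, str] | None:
    """Exact-match placement of a read: (chrom, 0-based start, strand)."""
    seq = seq.upper()
    rc = revcomp(seq)
    for chrom, host in host_sequences.items():
        i = host.find(seq)
        if i >= 0:
            return chrom, i, "+"
        i = host.find(rc)
        if i >= 0:
            return chrom, i, "-"
    return None


def readpair_integration(pairs: Iterable[tuple[str, str, str]],
                         viral_kmers: frozenset,
                         host_sequences: Mapping[str, str],
                         k: int = 25,
                         cluster_window: int = DEFAULT_CLUSTER_WINDOW,
                         min_support: int = DEFAULT_MIN_SUPPORT) -> list[IntegrationSite]:
    """Integration sites from read pairs with exactly one viral mate.

    The host mate of each such pair is placed by exact matching; mate
    positions are clustered within ``cluster_window`` bp per chromosome,
    and clusters with at least ``min_support`` pairs become sites whose
    position is the cluster boundary nearest the viral side (given by
    the mates' mapping strand).  Pairs with both or neither mate viral
    are ignored.
    """
    anchors: dict[str, list[tuple[int, int, str]]] = {}
    for _name, seq1, seq2 in pairs:
        v1 = is_viral_read(seq1, viral_kmers, k)
        v2 = is_viral_read(seq2, viral_kmers, k)
        if v1 == v2:
            continue
        host_mate = seq2 if v1 else seq1
        placed = place_read(host_mate, host_sequences)
        if placed is None:
            continue
        chrom, start, strand = placed
        anchors.setdefault(chrom, []).append((start, start + len(host_mate), strand))
    sites = []
    for chrom, placements in anchors.items():
        placements.sort()
        cluster: list[tuple[int, int, str]] = []
        for placement in placements + [(1 << 60, 1 << 60, ".")]:
            if cluster and placement[0] - cluster[-1][0] > cluster_window:
                site = _cluster_site(chrom, cluster, min_support)
                if site is not None:
                    sites.append(site)
                cluster = []
            cluster.append(placement)
        # sentinel cluster never reaches min_support alone
    return sites


def _cluster_site(chrom: str, cluster: list, min_support: int) -> IntegrationSite | None:
    real = [c for c in cluster if c[2] != "."]
    if len(real) < min_support:
        return None
    n_fwd = sum(1 for c in real if c[2] == "+")
    if n_fwd >= len(real) - n_fwd:
        pos = max(end for _s, end, _d in real)  # mates point right, junction at far end
    else:
        pos = min(start for start, _e, _d in real) + 1
    return IntegrationSite(chrom=chrom, pos=pos, orientation="unknown",
                           evidence="read_pairs", support=len(real))


def count_spanning_reads(pairs: Iterable[tuple[str, str, str]],
                         host_sequences: Mapping[str, str],
                         chrom: str, pos: int, margin: int = 5) -> int:
    """Reads whose exact host placement spans the junction coordinate.

    A read spans when its alignment covers ``pos`` with at least
    ``margin`` bases on each side; only non-chimeric placements count.
    """
    n = 0
    for _name, seq1, seq2 in pairs:
        for seq in (seq1, seq2):
            placed = place_read(seq, host_sequences)
            if placed is None:
                continue
            c, start, _strand = placed
            if c == chrom and start + margin <= pos - 1 < start + len(seq) - margin:
                n += 1
    return n


def junction_zygosity(spanning_read_count: int, junction_support_count: int) -> str:
    """Zygosity of an insertion from junction vs spanning evidence.

    A well-supported junction with no spanning reads means every allele
    carries the insertion; well-supported junction plus well-supported
    spanning reads means only some alleles do.
    """
    if spanning_read_count < 0 or junction_support_count < 0:
        raise ValueError("negative read count")
    if junction_support_count >= 3 and spanning_read_count == 0:
        return ALL_ALLELES
    if junction_support_count >= 3 and spanning_read_count >= 3:
        return PARTIAL
    return NO_CALL
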