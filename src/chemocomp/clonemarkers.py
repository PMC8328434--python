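"""In-silico tools for the rDNA clone-discrimination assay.

The study's ciliate clones are morphologically identical but carry divergent
ITS-1/ITS-2 regions between conserved rRNA genes.  This module reproduces
the computable parts of the assay: IUPAC-aware primer-site search, in-silico
PCR amplicon prediction, GC-clamp construction for DGGE-compatible primers,
and pairwise sequence divergence (p-distance after global alignment).

Amplicon coordinates are 0-based half-open internally; lengths include both
primer footprints, matching how Sanger-verified product sizes are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PrimerPair",
    "AmpliconResult",
    "reverse_complement",
    "find_primer_sites",
    "in_silico_pcr",
    "attach_gc_clamp",
    "pairwise_divergence",
    "read_fasta",
    "write_fasta",
    "PRIMER_3770F",
    "PRIMER_2104R",
    "PRIMER_ITS_F",
    "PRIMER_ITS_R",
    "GC_CLAMP",
    "PRIMER_3770F_GC",
    "DGGE_PAIR",
    "ITS_PAIR",
]

# Primers as synthesized (5'->3').  3770F/2104R bind the conserved regions
# flanking the hypervariable ITS-1/ITS-2 stretch; ITS F/R amplify the full
# ~2.8 kb 18S-ITS1-5.8S-ITS2-partial-28S fragment.
PRIMER_ITS_F = "GAAACTGCGAATGGCTC"
PRIMER_ITS_R = "TTGGTCCGTGTTTCAAGACG"
PRIMER_3770F = "GATCCGGTGAACCTTCTGGAC"
PRIMER_2104R = "CGGCGCTTTATCCTATTTTGGC"
#: 40-nt GC-rich 5' extension stabilising partial melting for DGGE.
GC_CLAMP = "CGCCCGCCGCGCCCCGCGCCCGTCCCGCCGCCCCCGCCCG"

_IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def _clean(seq: str, what: str = "sequence") -> str:
    s = "".join(str(seq).split()).upper()
    if not s:
        raise ValueError(f"empty {what}")
    bad = set(s) - set(_IUPAC)
    if bad:
        raise ValueError(f"illegal characters in {what}: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primer pair, both as synthesized (5'->3')."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward", _clean(self.forward, "forward primer"))
        object.__setattr__(self, "reverse", _clean(self.reverse, "reverse primer"))


DGGE_PAIR = PrimerPair("3770F/2104R", PRIMER_3770F, PRIMER_2104R)
ITS_PAIR = PrimerPair("ITS_F/ITS_R", PRIMER_ITS_F, PRIMER_ITS_R)


@dataclass(frozen=True)
class AmpliconResult:
    """One predicted PCR product on a template.

    ``start``/``end`` are 0-based half-open template coordinates spanning
    both primer footprints; ``length`` = end - start.
    """

    template_id: str
    start: int
    end: int
    forward_site_strand: str = "+"
    reverse_site_strand: str = "-"

    @property
    def length(self) -> int:
        return self.end - self.start

    def report_coordinates(self) -> tuple[int, int]:
        """1-based inclusive coordinates for human-readable reports."""
        return self.start + 1, self.end


def reverse_complement(seq: str) -> str:
    """Reverse complement, IUPAC ambiguity codes included; an involution."""
    return str(Seq(_clean(seq)).reverse_complement())


def _iupac_match(primer: str, window: str, max_mismatches: int) -> bool:
    mismatches = 0
    for p, t in zip(primer, window):
        if t not in _IUPAC[p]:
            mismatches += 1
            if mismatches > max_mismatches:
                return False
    return True


def find_primer_sites(
    template: str, primer: str, max_mismatches: int = 0
) -> list[tuple[int, str]]:
    """Find primer binding sites on both strands of a template.

    Returns (position, strand) pairs: forward-strand hits are matches of the
    primer itself at ``template[pos:pos+len]``; reverse-strand hits are
    matches of the primer's reverse complement (i.e. the primer anneals to
    the forward strand read 3'->5').  IUPAC codes in the primer match any of
    their expansions.  Exact matching is the default — the study's primers
    were designed on these very templates.
    """
    template = _clean(template, "template")
    primer = _clean(primer, "primer")
    if len(primer) > len(template):
        return []
    rc = reverse_complement(primer)
    hits: list[tuple[int, str]] = []
    for pos in range(len(template) - len(primer) + 1):
        window = template[pos : pos + len(primer)]
        if _iupac_match(primer, window, max_mismatches):
            hits.append((pos, "+"))
        if _iupac_match(rc, window, max_mismatches):
            hits.append((pos, "-"))
    return hits


def in_silico_pcr(
    template: str,
    pair: PrimerPair,
    max_len: int = 5000,
    max_mismatches: int = 0,
    template_id: str = "template",
) -> list[AmpliconResult]:
    """Predict PCR products of a primer pair on a template.

    A product forms wherever a forward-primer site lies upstream of a
    reverse-complemented reverse-primer site within ``max_len``; the amplicon
    spans both primer footprints inclusive.  Products from the pair binding
    in the opposite orientation (forward primer on the minus strand) are
    reported symmetrically.
    """
    template = _clean(template, "template")
    fwd_hits = find_primer_sites(template, pair.forward, max_mismatches)
    rev_hits = find_primer_sites(template, pair.reverse, max_mismatches)
    products = []
    for fpos, fstrand in fwd_hits:
        if fstrand != "+":
            continue
        for rpos, rstrand in rev_hits:
            if rstrand != "-":
                continue
            end = rpos + len(pair.reverse)
            if end <= fpos:
                continue
            length = end - fpos
            if length < len(pair.forward) + len(pair.reverse) or length > max_len:
                continue
            products.append(AmpliconResult(template_id, fpos, end))
    return sorted(products, key=lambda a: (a.start, a.end))


def attach_gc_clamp(primer: str, clamp: str = GC_CLAMP) -> str:
    """Prepend a GC clamp to a primer's 5' end (identity for an empty clamp)."""
    primer = _clean(primer, "primer")
    if not clamp:
        return primer
    return _clean(clamp, "clamp") + primer


PRIMER_3770F_GC = attach_gc_clamp(PRIMER_3770F)


def _default_aligner(match: float, mismatch: float, gap: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def pairwise_divergence(
    seq_a: str,
    seq_b: str,
    *,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> float:
    """p-distance between two sequences after global alignment.

    Aligns globally (default scores: match +1, mismatch -1, gap -2), then
    counts differing sites over aligned columns, excluding columns with a
    gap in either sequence.  Symmetric; zero iff the sequences are identical
    up to alignment.
    """
    a = _clean(seq_a, "sequence a")
    b = _clean(seq_b, "sequence b")
    aligner = _default_aligner(match, mismatch, gap)
    alignment = next(iter(aligner.align(a, b)))
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    compared = differing = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x != y:
            differing += 1
    if compared == 0:
        raise ValueError("no gap-free aligned columns to compare")
    return differing / compared


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str] | Iterable[tuple[str, str]], path) -> None:
    """Write sequences to FASTA (60-column wrapping)."""
    items = sequences.items() if isinstance(sequences, dict) else sequences
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(records, str(path), "fasta")
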