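"""Guide placement and amplicon sizing against reference sequences.

Locates protospacer/PAM sites on either strand of a DNA reference, computes
the predicted SpCas9 blunt-cut coordinate (3 bp upstream of the PAM on the
protospacer-carrying strand), and sizes PCR amplicons in silico.

All coordinates are 1-based and fully closed; every writer states this in
its header.  Degenerate IUPAC bases (only N is supported) match any base
when they appear in a query pattern and match nothing when they appear in
the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

COORDINATE_NOTE = "coordinates are 1-based, fully closed"

_DNA = set("ACGTN")


class AmbiguityError(ValueError):
    """Raised when a search yields more distinct sites than permitted."""


@dataclass(frozen=True)
class ReferenceSeq:
    """A named DNA reference; ``sequence`` is uppercase IUPAC over ACGTN."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"reference {self.id!r} is empty")
        bad = set(seq) - _DNA
        if bad:
            raise ValueError(f"reference {self.id!r} has non-ACGTN bases: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GuideHit:
    """A protospacer match.

    ``start``/``end`` delimit the protospacer on sense coordinates
    (1-based closed) regardless of strand; ``pam_start`` is the leftmost
    sense coordinate of the 3-nt PAM.
    """

    start: int
    end: int
    strand: str  # "sense" | "antisense"
    pam_start: int


@dataclass(frozen=True)
class GuideSpec:
    name: str
    protospacer: str
    strand: str
    pam: str
    cut_site: int

    def __post_init__(self) -> None:
        if not (len(self.pam) == 3 and self.pam[1:] == "GG"):
            raise ValueError(f"guide {self.name!r}: PAM {self.pam!r} does not match NGG")
        if self.strand not in ("sense", "antisense"):
            raise ValueError(f"guide {self.name!r}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class PrimerPair:
    """Forward primer written on sense, reverse written 5'->3' on antisense."""

    name: str
    forward: str
    reverse: str
    expected_len: int | None = None

    def __post_init__(self) -> None:
        if len(self.forward) < 15 or len(self.reverse) < 15:
            raise ValueError(f"primer pair {self.name!r}: primers must be >= 15 nt")
        if self.expected_len is not None and self.expected_len < len(self.forward) + len(self.reverse):
            raise ValueError(f"primer pair {self.name!r}: expected_len shorter than the primers")


@dataclass(frozen=True)
class Amplicon:
    start: int
    end: int
    length: int
    ambiguous: bool = False
    siblings: tuple = field(default_factory=tuple)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _pattern_match(ref: str, pattern: str, pos0: int, max_mismatch: int = 0) -> bool:
    """Match ``pattern`` at 0-based ``pos0``; N in pattern is a wildcard, N in ref never matches."""
    mm = 0
    for i, p in enumerate(pattern):
        r = ref[pos0 + i]
        if r == "N" or (p != "N" and p != r):
            mm += 1
            if mm > max_mismatch:
                return False
    return True


def _scan(ref: str, pattern: str, max_mismatch: int = 0) -> list[int]:
    """All 0-based start positions where ``pattern`` matches ``ref``."""
    n, m = len(ref), len(pattern)
    return [i for i in range(n - m + 1) if _pattern_match(ref, pattern, i, max_mismatch)]


def find_protospacer(
    ref: ReferenceSeq,
    protospacer: str,
    pam_pattern: str = "NGG",
    max_hits: int = 10,
) -> list[GuideHit]:
    """Locate ``protospacer`` with ``pam_pattern`` immediately 3' on either strand.

    Returns hits sorted by sense coordinate.  No hit yields an empty list
    with a warning; more than ``max_hits`` raises :class:`AmbiguityError`.
    """
    protospacer = protospacer.upper()
    if len(protospacer) < 17:
        raise ValueError("protospacer must be >= 17 nt")
    seq = ref.sequence
    L = len(protospacer)
    hits: list[GuideHit] = []
    # sense: protospacer then PAM, left to right
    for i in _scan(seq, protospacer + pam_pattern.upper()):
        hits.append(GuideHit(start=i + 1, end=i + L, strand="sense", pam_start=i + L + 1))
    # antisense: search revcomp(PAM + protospacer read 5'->3' on antisense)
    # on the sense strand; PAM sits immediately left of the protospacer span.
    rc = revcomp(protospacer + pam_pattern.upper())
    for i in _scan(seq, rc):
        hits.append(GuideHit(start=i + 4, end=i + 3 + L, strand="antisense", pam_start=i + 1))
    hits.sort(key=lambda h: (h.start, h.strand))
    if not hits:
        warnings.warn(f"protospacer {protospacer!r} not found in {ref.id}", stacklevel=2)
    if len(hits) > max_hits:
        raise AmbiguityError(f"{len(hits)} hits for {protospacer!r} in {ref.id} (max_hits={max_hits})")
    return hits


def cut_site(hit: GuideHit, ref_length: int) -> int:
    """Predicted blunt-cut coordinate: the base 3 bp upstream of the PAM.

    Measured along the protospacer-carrying strand and reported on sense
    coordinates.  The cut falls between this base and its PAM-proximal
    neighbour.
    """
    if hit.strand == "sense":
        c = hit.pam_start - 3
    else:
        # PAM read 5'->3' on the antisense strand starts at sense pam_start+2;
        # 3 bp upstream along that strand moves towards larger sense coords.
        c = (hit.pam_start + 2) + 3
    if not 1 <= c <= ref_length or hit.pam_start < 1 or hit.pam_start + 2 > ref_length:
        raise ValueError(f"PAM within 3 bp of the sequence end (cut would be {c})")
    return c


def locate_guides(ref: ReferenceSeq, guides: Iterable[tuple[str, str]]) -> list[GuideSpec]:
    """Resolve (name, protospacer) queries to :class:`GuideSpec` records."""
    out: list[GuideSpec] = []
    for name, proto in guides:
        for hit in find_protospacer(ref, proto):
            if hit.strand == "sense":
                pam = ref.sequence[hit.pam_start - 1 : hit.pam_start + 2]
            else:
                pam = revcomp(ref.sequence[hit.pam_start - 1 : hit.pam_start + 2])
            out.append(
                GuideSpec(name=name, protospacer=proto.upper(), strand=hit.strand,
                          pam=pam, cut_site=cut_site(hit, len(ref)))
            )
    return out


def insilico_pcr(ref: ReferenceSeq, pair: PrimerPair, max_mismatch: int = 0) -> Amplicon:
    """Size the amplicon of ``pair`` on ``ref``.

    The forward primer is searched on sense, the reverse primer as its
    reverse complement on sense downstream of the forward site; amplicon
    length spans the forward 5' coordinate through the downstream edge of
    the reverse binding site, inclusive.
    """
    seq = ref.sequence
    fwd_sites = _scan(seq, pair.forward.upper(), max_mismatch)
    rev_sites = _scan(seq, revcomp(pair.reverse.upper()), max_mismatch)
    rlen = len(pair.reverse)
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            if r > f:  # reverse site strictly downstream
                start, end = f + 1, r + rlen
                products.append(Amplicon(start=start, end=end, length=end - start + 1))
    if not products:
        raise ValueError(f"no productive pairing for primer pair {pair.name!r} on {ref.id}")
    if len(products) > 1:
        warnings.warn(
            f"{len(products)} productive pairings for {pair.name!r} on {ref.id}; reporting the shortest",
            stacklevel=2,
        )
        products.sort(key=lambda a: a.length)
        first = products[0]
        return Amplicon(start=first.start, end=first.end, length=first.length,
                        ambiguous=True, siblings=tuple(products[1:]))
    return products[0]


# ---------------------------------------------------------------------------
# file I/O

def read_fasta(path: str | Path) -> list[ReferenceSeq]:
    return [ReferenceSeq(id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(refs: Iterable[ReferenceSeq], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.id}\n{ref.sequence}\n")


def read_guide_sheet(path: str | Path) -> list[tuple[str, str]]:
    """TSV with columns (name, sequence[, direction])."""
    df = pd.read_csv(path, sep="\t")
    return list(zip(df["name"], df["sequence"]))


def read_primer_sheet(path: str | Path) -> list[PrimerPair]:
    """TSV with columns (name, forward, reverse[, expected_len])."""
    df = pd.read_csv(path, sep="\t")
    pairs = []
    for _, row in df.iterrows():
        exp = int(row["expected_len"]) if "expected_len" in df.columns and pd.notna(row.get("expected_len")) else None
        pairs.append(PrimerPair(name=row["name"], forward=row["forward"], reverse=row["reverse"], expected_len=exp))
    return pairs


def guides_table(ref: ReferenceSeq, specs: Iterable[GuideSpec]) -> pd.DataFrame:
    rows = [
        {"name": g.name, "ref_id": ref.id, "strand": g.strand, "pam": g.pam, "cut_site": g.cut_site}
        for g in specs
    ]
    df = pd.DataFrame(rows)
    df.attrs["coordinates"] = COORDINATE_NOTE
    return df


def amplicon_table(ref: ReferenceSeq, named: Iterable[tuple[str, Amplicon]]) -> pd.DataFrame:
    rows = [
        {"name": name, "ref_id": ref.id, "start": a.start, "end": a.end,
         "length": a.length, "ambiguous": a.ambiguous}
        for name, a in named
    ]
    df = pd.DataFrame(rows)
    df.attrs["coordinates"] = COORDINATE_NOTE
    return df
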