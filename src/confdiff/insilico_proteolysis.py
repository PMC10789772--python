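"""In-silico limited proteolysis: trypsin sites, fragments, domain maps
and relative peptide scores.

Trypsin specificity follows the Keil rule — cleavage C-terminal to Lys or
Arg except when the next residue is Pro.  Limited (partial) digestion is
modelled by enumerating fragments bounded by the sequence ends or by
cleavage sites, allowing missed internal sites; fragments are then mapped
onto annotated domains (e.g. N-domain / linker / C-domain) as overlap
fractions.  Band-level mass-spectrometry protein scores are normalised by
dividing each peptide's score by the score of the same peptide in the
undigested "Total" band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ProteinSequence",
    "Fragment",
    "RelativeScore",
    "read_fasta",
    "predict_trypsin_sites",
    "enumerate_fragments",
    "map_fragment_to_domains",
    "relative_peptide_scores",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ProteinSequence:
    """A protein sequence with optional 1-based inclusive domain annotation."""

    identifier: str
    residues: str
    domains: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.residues)
        spans = sorted((first, last, label) for label, first, last in self.domains)
        prev_end = 0
        for first, last, label in spans:
            if not (1 <= first <= last <= n):
                raise ValueError(f"domain {label}: span {first}-{last} outside 1..{n}")
            if first <= prev_end:
                raise ValueError(f"domain {label} overlaps a previous domain")
            prev_end = last

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Fragment:
    """A proteolytic fragment, 1-based inclusive span of its parent sequence."""

    start: int
    end: int
    sequence: str
    band: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid fragment span {self.start}-{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("fragment sequence length disagrees with its span")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class RelativeScore:
    """A peptide's band prot-score divided by its score in the Total band."""

    band: str
    peptide: tuple[int, int]
    prot_score: float
    total_score: float | None
    relative_score: float | None
    status: str = "ok"  # "ok" | "missing_total" | "zero_total"


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    return [
        ProteinSequence(identifier=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def predict_trypsin_sites(seq: ProteinSequence | str) -> list[int]:
    """Trypsin cleavage positions under the Keil rule.

    Returns sorted 1-based positions i meaning cleavage between residues i
    and i+1: after every K or R whose next residue is not P.  The
    C-terminal residue is never a site.  Non-standard letters provoke a
    warning and are treated as non-cleavable.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else str(seq).upper()
    unknown = set(residues) - STANDARD_AA
    if unknown:
        warnings.warn(
            f"non-standard letters treated as non-cleavable: {sorted(unknown)}",
            stacklevel=2,
        )
    sites = []
    for i in range(len(residues) - 1):  # last residue excluded
        if residues[i] in "KR" and residues[i + 1] != "P":
            sites.append(i + 1)
    return sites


def enumerate_fragments(
    seq: ProteinSequence | str,
    sites: list[int] | None = None,
    max_missed: int | None = None,
    band: str = "",
) -> list[Fragment]:
    """All digest fragments bounded by sequence ends or cleavage sites.

    ``max_missed`` caps the number of uncut internal sites per fragment:
    0 models complete digestion, ``None`` (default) allows every partial
    product, which is what limited proteolysis produces.  Fragments are
    ordered by start, then end.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else str(seq).upper()
    if sites is None:
        sites = predict_trypsin_sites(residues)
    boundaries = [0] + sorted(sites) + [len(residues)]
    frags = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, len(boundaries)):
            internal = j - i - 1
            if max_missed is not None and internal > max_missed:
                break
            start, end = boundaries[i] + 1, boundaries[j]
            frags.append(
                Fragment(start=start, end=end, sequence=residues[start - 1 : end], band=band)
            )
    return frags


def map_fragment_to_domains(
    f: Fragment, seq: ProteinSequence
) -> list[tuple[str, float]]:
    """Fraction of a fragment falling in each annotated domain.

    Returns ``(label, overlap_residues / fragment_length)`` for every
    domain the fragment touches; fractions sum to at most 1 (unannotated
    gaps are allowed).  A fragment wholly outside the annotation maps to
    an empty list.
    """
    if f.end > len(seq):
        raise ValueError("fragment extends beyond the sequence")
    out = []
    for label, first, last in seq.domains:
        overlap = min(f.end, last) - max(f.start, first) + 1
        if overlap > 0:
            out.append((label, overlap / len(f)))
    return out


def relative_peptide_scores(
    band_scores: pd.DataFrame, total_band: str = "Total"
) -> list[RelativeScore]:
    """Normalise band-level peptide prot-scores by the Total band.

    ``band_scores`` needs columns ``band``, ``peptide_start``,
    ``peptide_end``, ``prot_score``; peptides are keyed by their span.
    Each non-Total row yields its prot-score divided by the Total score of
    the same peptide.  A peptide absent from Total is flagged
    (``status="missing_total"``, no score); a zero Total score yields an
    explicit ``zero_total`` division-undefined entry.
    """
    required = {"band", "peptide_start", "peptide_end", "prot_score"}
    missing = required - set(band_scores.columns)
    if missing:
        raise ValueError(f"score table lacks columns: {sorted(missing)}")
    if (band_scores["prot_score"] < 0).any():
        raise ValueError("prot_score must be nonnegative")
    totals = {
        (int(r.peptide_start), int(r.peptide_end)): float(r.prot_score)
        for r in band_scores[band_scores["band"] == total_band].itertuples()
    }
    if not totals:
        raise ValueError(f"total band {total_band!r} absent from the score table")
    out = []
    for r in band_scores[band_scores["band"] != total_band].itertuples():
        pep = (int(r.peptide_start), int(r.peptide_end))
        score = float(r.prot_score)
        total = totals.get(pep)
        if total is None:
            out.append(RelativeScore(r.band, pep, score, None, None, "missing_total"))
        elif total == 0.0:
            out.append(RelativeScore(r.band, pep, score, 0.0, None, "zero_total"))
        else:
            out.append(RelativeScore(r.band, pep, score, total, score / total))
    return out
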