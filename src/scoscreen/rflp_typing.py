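"""In-silico PCR-RFLP typing of ITS amplicons.

A restriction enzyme is modelled as a recognition site plus a cut offset on
the top strand (0-based, between-base coordinates: a cut at position *k*
splits a sequence into ``[0, k)`` and ``[k, len)``).  The two enzymes used
for kefir-yeast ITS typing are HaeIII (GG^CC) and RsaI (GT^AC); both are
palindromic blunt cutters, so scanning the top strand alone is complete.

Gel-derived reference patterns carry estimation error, so fragment matching
uses a base-pair tolerance (default 20 bp, the resolution at which published
gel patterns stay self-consistent).  In-silico digests, by contrast, are
exact: fragment lengths always sum to the input length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "DnaSequence",
    "RestrictionEnzyme",
    "DigestPattern",
    "MatchResult",
    "HAEIII",
    "RSAI",
    "DEFAULT_ENZYMES",
    "DEFAULT_GEL_TOL_BP",
    "find_sites",
    "digest",
    "match_pattern",
    "pattern_consistency",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "load_pattern_db",
    "pattern_from_dict",
]

_VALID_BASES = frozenset("ACGT")

#: default gel-estimation tolerance in base pairs
DEFAULT_GEL_TOL_BP = 20


@dataclass(frozen=True)
class DnaSequence:
    """An unambiguous DNA sequence (A/C/G/T, stored uppercase)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        s = self.seq.upper()
        object.__setattr__(self, "seq", s)
        if not s:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(s) - _VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGT characters: "
                f"{sorted(bad)} (ambiguity codes are not supported)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Recognition site and top-strand cut offset of a restriction enzyme."""

    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.recognition_site.upper()
        object.__setattr__(self, "recognition_site", site)
        if len(site) < 4:
            raise ValueError(f"{self.name}: recognition site must be >= 4 bp")
        if set(site) - _VALID_BASES:
            raise ValueError(f"{self.name}: site must be unambiguous DNA")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError(
                f"{self.name}: cut offset {self.cut_offset} outside site"
            )


HAEIII = RestrictionEnzyme("HaeIII", "GGCC", 2)
RSAI = RestrictionEnzyme("RsaI", "GTAC", 2)
DEFAULT_ENZYMES: dict[str, RestrictionEnzyme] = {e.name: e for e in (HAEIII, RSAI)}


def reverse_complement(seq: DnaSequence) -> DnaSequence:
    return DnaSequence(
        id=f"{seq.id}_rc", seq=str(Seq(seq.seq).reverse_complement())
    )


def find_sites(seq: DnaSequence, enzyme: RestrictionEnzyme) -> list[int]:
    """Cut positions (0-based, between-base), strictly increasing.

    Every occurrence of the recognition site, including overlapping ones,
    contributes one cut at ``occurrence start + cut_offset``.
    """
    site = enzyme.recognition_site
    cuts = []
    start = seq.seq.find(site)
    while start != -1:
        cuts.append(start + enzyme.cut_offset)
        start = seq.seq.find(site, start + 1)
    return cuts


def digest(seq: DnaSequence, enzyme: RestrictionEnzyme) -> list[int]:
    """Fragment lengths after cutting at all sites, sorted descending.

    Lengths always sum to the sequence length; an uncut sequence yields a
    single full-length fragment.
    """
    cuts = find_sites(seq, enzyme)
    bounds = [0, *cuts, len(seq)]
    fragments = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    return sorted(fragments, reverse=True)


@dataclass(frozen=True)
class DigestPattern:
    """Amplicon size and per-enzyme fragment-length lists for one strain."""

    strain_id: str
    amplicon_bp: int
    fragments: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.amplicon_bp <= 0:
            raise ValueError("amplicon size must be > 0")
        normalized = {}
        for enzyme, frags in self.fragments.items():
            if any(f <= 0 for f in frags):
                raise ValueError(
                    f"{self.strain_id}/{enzyme}: fragment lengths must be > 0"
                )
            normalized[enzyme] = sorted(int(f) for f in frags)[::-1]
        object.__setattr__(self, "fragments", normalized)


@dataclass(frozen=True)
class MatchResult:
    """Scored comparison of an observed pattern against one reference."""

    strain_id: str
    score: int
    consistent: bool
    assignments: dict[str, list[tuple[int | None, int | None]]]


def pattern_consistency(
    pattern: DigestPattern, tol_bp: int = DEFAULT_GEL_TOL_BP
) -> dict[str, bool]:
    """Per enzyme: do the fragments sum to the amplicon size within tol_bp?"""
    return {
        enzyme: abs(sum(frags) - pattern.amplicon_bp) <= tol_bp
        for enzyme, frags in pattern.fragments.items()
    }


def _score_one(
    observed: Sequence[int], reference: Sequence[int], tol_bp: int
) -> tuple[int, bool, list[tuple[int | None, int | None]]]:
    """Greedy largest-to-largest fragment assignment for one enzyme.

    Paired fragments contribute their absolute size difference; each
    unmatched fragment (either side) contributes ``tol_bp + its length``.
    """
    obs = sorted(observed, reverse=True)
    ref = sorted(reference, reverse=True)
    pairs: list[tuple[int | None, int | None]] = []
    score = 0
    for o, r in zip(obs, ref):
        pairs.append((o, r))
        score += abs(o - r)
    for o in obs[len(ref):]:
        pairs.append((o, None))
        score += tol_bp + o
    for r in ref[len(obs):]:
        pairs.append((None, r))
        score += tol_bp + r
    consistent = len(obs) == len(ref) and all(
        abs(o - r) <= tol_bp for o, r in zip(obs, ref)
    )
    return score, consistent, pairs


def match_pattern(
    observed: DigestPattern,
    db: Sequence[DigestPattern],
    tol_bp: int = DEFAULT_GEL_TOL_BP,
) -> list[MatchResult]:
    """Rank reference patterns by total absolute bp discrepancy.

    For each candidate, fragments are assigned greedily largest-to-largest
    per enzyme (over the union of enzyme keys).  A candidate is flagged
    ``consistent`` when, for every enzyme, fragment counts agree and every
    assigned pair differs by at most ``tol_bp``.  Sorted by ascending score,
    ties broken by strain id.
    """
    if not db:
        raise ValueError("reference pattern database is empty")
    if tol_bp < 0:
        raise ValueError("tol_bp must be >= 0")
    results = []
    for ref in db:
        enzymes = sorted(set(observed.fragments) | set(ref.fragments))
        total = 0
        all_consistent = True
        assignments = {}
        for enzyme in enzymes:
            score, ok, pairs = _score_one(
                observed.fragments.get(enzyme, []),
                ref.fragments.get(enzyme, []),
                tol_bp,
            )
            total += score
            all_consistent &= ok
            assignments[enzyme] = pairs
        results.append(
            MatchResult(
                strain_id=ref.strain_id,
                score=total,
                consistent=all_consistent,
                assignments=assignments,
            )
        )
    return sorted(results, key=lambda r: (r.score, r.strain_id))


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_fasta(source: str | Path) -> list[DnaSequence]:
    """Read sequences from a FASTA file (validated, uppercased)."""
    return [
        DnaSequence(id=rec.id, seq=str(rec.seq))
        for rec in SeqIO.parse(str(source), "fasta")
    ]


def write_fasta(sequences: Iterable[DnaSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.seq), 60):
                fh.write(s.seq[i : i + 60] + "\n")


def pattern_from_dict(doc: dict) -> DigestPattern:
    """Build a pattern from the JSON schema {strain, amplicon_bp, fragments}."""
    for key in ("strain", "amplicon_bp", "fragments"):
        if key not in doc:
            raise ValueError(f"pattern record missing field {key!r}")
    return DigestPattern(
        strain_id=str(doc["strain"]),
        amplicon_bp=int(doc["amplicon_bp"]),
        fragments={str(k): list(v) for k, v in doc["fragments"].items()},
    )


def load_pattern_db(source: str | Path) -> list[DigestPattern]:
    """Load a reference pattern database from JSON.

    Accepts either ``{"patterns": [...]}`` or a bare list of records.
    """
    doc = json.loads(Path(source).read_text())
    records = doc["patterns"] if isinstance(doc, dict) else doc
    return [pattern_from_dict(rec) for rec in records]
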