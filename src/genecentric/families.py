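"""Reference-anchored construction of metabolic gene families.

Candidate genes are pulled from an annotated pangenome FASTA by
case-insensitive header matching (with negative patterns taking
precedence), filtered by length relative to an experimentally validated
reference enzyme, gap-filtered after alignment, and finally delimited on
a neighbor-joining tree: the family is the largest clade around the
reference in which every leaf stays within a path distance ``d_max`` of
the reference.  Trees are built from pairwise p-distances over gap-free
column pairs and midpoint-rooted, a deliberately light-weight stand-in
for full maximum-likelihood reconstruction — the delimitation contract
is distance-based either way.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

GAP_CHARS = frozenset("-.")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    """Header-matched candidate records from one pangenome FASTA."""

    records: list[tuple[str, str]]          # (header, sequence)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [h.split()[0] for h, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in candidate set")
        for h, s in self.records:
            if not s:
                raise ValueError(f"empty sequence for {h.split()[0]}")

    @property
    def ids(self) -> list[str]:
        return [h.split()[0] for h, _ in self.records]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class Msa:
    """A protein multiple alignment with equal-length rows."""

    ids: list[str]
    rows: list[str]
    reference_id: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if self.rows:
            ncol = len(self.rows[0])
            if any(len(r) != ncol for r in self.rows):
                raise ValueError("alignment rows have unequal column counts")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def gap_fraction(self, i: int) -> float:
        row = self.rows[i]
        return sum(c in GAP_CHARS for c in row) / len(row)

    @classmethod
    def from_candidates(cls, candidates: CandidateSet, name: str = "") -> "Msa":
        """Stack equal-length sequences as a trivial alignment.

        Family members generated by point substitution (and real MSAs
        read from aligned FASTA) already share a column space; anything
        else must be aligned upstream.
        """
        seqs = [s for _, s in candidates.records]
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError(
                "sequences have unequal lengths; provide an aligned FASTA")
        return cls(ids=candidates.ids, rows=seqs, name=name)


@dataclass
class GeneFamily:
    """A delimited gene family: members, lengths and size S.

    The reference enzyme anchors delimitation but does not count toward
    S unless it is a genuine pangenome member.
    """

    family_id: str
    member_ids: list[str]
    member_lengths_aa: dict[str, int] = field(default_factory=dict)
    reference_id: str = ""
    pathway_tag: str = ""

    @property
    def s(self) -> int:
        return len(self.member_ids)

    @property
    def member_lengths_nt(self) -> dict[str, int]:
        return {m: 3 * la for m, la in self.member_lengths_aa.items()}

    @property
    def mean_length_nt(self) -> float:
        if not self.member_ids:
            raise ValueError(f"family {self.family_id} has no members")
        return 3.0 * float(np.mean([self.member_lengths_aa[m] for m in self.member_ids]))


# ---------------------------------------------------------------------------
# extraction and filtering
# ---------------------------------------------------------------------------

def read_fasta(source: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA (path or raw text) into (header, seq) pairs."""
    if isinstance(source, Path) or "\n" not in str(source):
        handle = open(source)
    else:
        handle = io.StringIO(str(source))
    with handle:
        return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]


def extract_candidates(
    fasta: str | Path | list[tuple[str, str]],
    include_patterns: list[str],
    exclude_patterns: list[str] | None = None,
    provenance: str = "",
) -> CandidateSet:
    """Select records whose header matches an include pattern.

    Patterns are case-insensitive regular expressions searched anywhere
    in the header (plain substrings work unchanged); a record matching
    any exclude pattern is dropped regardless of includes.
    """
    if not include_patterns:
        raise ValueError("at least one include pattern is required")
    records = fasta if isinstance(fasta, list) else read_fasta(fasta)
    inc = [re.compile(p, re.IGNORECASE) for p in include_patterns]
    exc = [re.compile(p, re.IGNORECASE) for p in (exclude_patterns or [])]
    kept = [
        (h, s) for h, s in records
        if any(p.search(h) for p in inc) and not any(p.search(h) for p in exc)
    ]
    if not kept:
        warnings.warn(f"no headers matched include patterns {include_patterns}")
    return CandidateSet(records=kept, provenance=provenance)


def filter_by_length(
    candidates: CandidateSet,
    reference_length: int,
    min_frac: float = 0.5,
    max_frac: float = 1.5,
) -> CandidateSet:
    """Keep sequences within [min_frac, max_frac] x reference length.

    Bounds are inclusive; fractional bounds are applied to the reference
    protein length in amino acids.
    """
    if reference_length <= 0:
        raise ValueError("reference_length must be > 0")
    if not 0 < min_frac <= max_frac:
        raise ValueError("require 0 < min_frac <= max_frac")
    lo, hi = min_frac * reference_length, max_frac * reference_length
    kept = [(h, s) for h, s in candidates.records if lo <= len(s) <= hi]
    return CandidateSet(records=kept, provenance=candidates.provenance)


def gap_filter(msa: Msa, max_gap_frac: float = 0.30) -> Msa:
    """Drop alignment rows with a gap fraction at or above the cutoff.

    The boundary is excluded: a row with exactly ``max_gap_frac`` gaps
    is removed.
    """
    keep = [i for i in range(len(msa.ids)) if msa.gap_fraction(i) < max_gap_frac]
    if not keep:
        raise ValueError(
            f"gap filter removed every sequence of family {msa.name or '<unnamed>'}")
    return Msa(ids=[msa.ids[i] for i in keep], rows=[msa.rows[i] for i in keep],
               reference_id=msa.reference_id if msa.reference_id in
               {msa.ids[i] for i in keep} else None, name=msa.name)


# ---------------------------------------------------------------------------
# reference anchoring
# ---------------------------------------------------------------------------

def _msa_consensus(msa: Msa) -> str:
    """Column-wise majority residue (gaps lose ties)."""
    cols = np.array([list(r) for r in msa.rows]).T
    out = []
    for col in cols:
        residues = [c for c in col if c not in GAP_CHARS]
        if residues:
            vals, counts = np.unique(residues, return_counts=True)
            out.append(vals[np.argmax(counts)])
        else:
            out.append("X")
    return "".join(out)


def anchor_reference(msa: Msa, reference_id: str, reference_seq: str) -> Msa:
    """Thread the validated reference enzyme into the alignment columns.

    A profile-to-sequence step: the reference is globally aligned to the
    column consensus; columns where the reference inserts residues become
    new all-gap columns for the existing rows.
    """
    if not reference_seq:
        raise ValueError("reference sequence is empty")
    if reference_id in msa.ids:
        raise ValueError(f"reference id {reference_id!r} collides with a member id")
    consensus = _msa_consensus(msa)
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    aligner.substitution_matrix = None
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aln = aligner.align(consensus, reference_seq)[0]
    cons_aln, ref_aln = str(aln[0]), str(aln[1])

    new_rows = [[] for _ in msa.rows]
    ref_row = []
    col = 0
    for c_char, r_char in zip(cons_aln, ref_aln):
        if c_char == "-":            # insertion in reference: new gap column
            for out in new_rows:
                out.append("-")
            ref_row.append(r_char)
        else:
            for out, row in zip(new_rows, msa.rows):
                out.append(row[col])
            ref_row.append(r_char)   # '-' where reference skips this column
            col += 1
    return Msa(ids=msa.ids + [reference_id],
               rows=["".join(r) for r in new_rows] + ["".join(ref_row)],
               reference_id=reference_id, name=msa.name)


# ---------------------------------------------------------------------------
# distance tree and delimitation
# ---------------------------------------------------------------------------

def p_distance_matrix(msa: Msa) -> DistanceMatrix:
    """Pairwise p-distances over gap-free column pairs.

    For each sequence pair only columns where neither row has a gap are
    compared; the distance is the fraction of differing residues.  Pairs
    with no comparable columns get distance 1.
    """
    arr = np.array([list(r) for r in msa.rows])
    gaps = np.isin(arr, list(GAP_CHARS))
    n = len(msa.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gaps[i] & ~gaps[j]
            total = int(ok.sum())
            dist = float((arr[i, ok] != arr[j, ok]).mean()) if total else 1.0
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids=msa.ids)


def build_distance_tree(msa: Msa) -> TreeNode:
    """Neighbor-joining tree from p-distances, negative branches clamped."""
    if len(msa.ids) < 3:
        raise ValueError("need at least 3 sequences to build a tree")
    dm = p_distance_matrix(msa)
    return nj(dm, neg_as_zero=True)


def _midpoint_root(tree: TreeNode) -> TreeNode:
    # identical leaf sets with all-zero branches have no midpoint; the
    # unrooted tree already answers every distance query in that case
    try:
        return tree.root_at_midpoint()
    except Exception:
        return tree


def delimit_family(
    tree: TreeNode,
    reference_id: str,
    d_max: float = 0.6,
    family_id: str = "",
    member_lengths_aa: dict[str, int] | None = None,
    pathway_tag: str = "",
) -> GeneFamily:
    """Delimit a family as the largest reference-centred clade.

    On the midpoint-rooted tree, walk the ancestors of the reference
    leaf from the tip toward the root and keep the largest clade in
    which every leaf lies within path distance ``d_max`` of the
    reference.  The reference itself is removed from the membership and
    S recomputed.
    """
    rooted = _midpoint_root(tree)
    try:
        ref = rooted.find(reference_id)
    except Exception as exc:
        raise ValueError(f"reference {reference_id!r} is not a leaf") from exc

    dist_to_ref = {t.name: ref.distance(t) for t in rooted.tips()}
    best_tips = [reference_id]
    node = ref
    while node.parent is not None:
        node = node.parent
        tips = [t.name for t in node.tips()]
        if all(dist_to_ref[t] <= d_max for t in tips):
            best_tips = tips
        else:
            break
    members = sorted(t for t in best_tips if t != reference_id)
    if not members:
        warnings.warn(
            f"family {family_id or reference_id}: no leaf within d_max={d_max} "
            "of the reference; returning an empty family")
    lengths = {m: (member_lengths_aa or {}).get(m, 0) for m in members}
    return GeneFamily(family_id=family_id or reference_id, member_ids=members,
                      member_lengths_aa=lengths, reference_id=reference_id,
                      pathway_tag=pathway_tag)


# ---------------------------------------------------------------------------
# end-to-end builder
# ---------------------------------------------------------------------------

def build_family(
    fasta: str | Path | list[tuple[str, str]],
    family_id: str,
    include_patterns: list[str],
    reference_id: str,
    reference_seq: str,
    exclude_patterns: list[str] | None = None,
    length_frac_bounds: tuple[float, float] = (0.5, 1.5),
    max_gap_frac: float = 0.30,
    d_max: float = 0.6,
    pathway_tag: str = "",
) -> GeneFamily:
    """Run extract -> length filter -> gap filter -> anchor -> tree -> delimit."""
    cand = extract_candidates(fasta, include_patterns, exclude_patterns,
                              provenance=str(family_id))
    cand = filter_by_length(cand, len(reference_seq), *length_frac_bounds)
    lengths = {h.split()[0]: len(s.replace("-", "")) for h, s in cand.records}
    msa = Msa.from_candidates(cand, name=family_id)
    msa = gap_filter(msa, max_gap_frac)
    msa = anchor_reference(msa, reference_id, reference_seq)
    tree = build_distance_tree(msa)
    fam = delimit_family(tree, reference_id, d_max, family_id=family_id,
                         member_lengths_aa=lengths, pathway_tag=pathway_tag)
    return fam


def families_to_frame(families: list[GeneFamily]) -> pd.DataFrame:
    """Family metadata TSV shape: one row per member gene."""
    rows = []
    for f in families:
        for m in f.member_ids:
            la = f.member_lengths_aa.get(m, 0)
            rows.append((f.family_id, m, la, 3 * la, m == f.reference_id,
                         f.pathway_tag))
    return pd.DataFrame(rows, columns=["family_id", "member_id", "length_aa",
                                       "length_nt", "is_reference", "pathway_tag"])
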