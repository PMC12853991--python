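"""Synthetic inputs with known ground truth for every pipeline stage.

The real analysis consumes outputs of external tools (protein aligners,
taxonomic profilers, profile-HMM scanners) applied to public cohorts and
genome collections.  This module emulates every one of those file shapes
with configurable ground truth so the downstream stages — family
building, RPKSM quantification, taxon-table cleaning, differential
testing and genome/plasmid screening — can be exercised and validated
end to end without any external download.

Ground truth is explicit: hit counts for a gene family are Poisson with
mean ``a_fs * S_f * Lbar_f(kb) * lib_s / 1e6`` so that the expected
RPKSM of family *f* in sample *s* equals the configured concentration
``a_fs`` exactly; genome carriers are a fixed-size random subset so the
configured prevalence is recovered sharply; noise (sub-threshold hits,
secondary hits, partial-coverage scan hits) is injected at stated rates
and always violates at least one downstream filter.

All randomness flows from a single integer seed; identical seeds and
configurations yield byte-identical output files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .study import two_group_design

AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# Enzyme products used as header annotations for synthetic families.
# Realistic names from the butyrate / short-chain-alcohol / TMA / methane
# pathways the pipeline targets; cycled with an index suffix if more
# families are requested than names available.
_PRODUCT_NAMES = [
    "butyrate kinase",
    "phosphate butyryltransferase",
    "butyryl-CoA dehydrogenase",
    "butyryl-CoA:acetate CoA-transferase",
    "crotonyl-CoA reductase",
    "bifunctional acetaldehyde-CoA/alcohol dehydrogenase",
    "CoA-acylating propionaldehyde dehydrogenase",
    "propanol dehydrogenase",
    "propanediol dehydratase large subunit",
    "propanediol dehydratase medium subunit",
    "propanediol dehydratase small subunit",
    "aldehyde reductase Ahr",
    "alcohol dehydrogenase YahK",
    "aldehyde dehydrogenase B",
    "acetaldehyde dehydrogenase MhpF",
    "choline trimethylamine-lyase",
    "trimethylamine-N-oxide reductase TorA",
    "trimethylamine-N-oxide reductase TorZ",
    "methyl-coenzyme M reductase alpha subunit",
    "methyl-coenzyme M reductase II alpha subunit",
    "heterodisulfide reductase subunit A",
    "tetrahydromethanopterin S-methyltransferase subunit A",
    "methanol corrinoid protein MtaB",
    "trimethylamine methyltransferase MttB",
]

_USCG_PRODUCTS = [
    "arginyl-tRNA synthetase ArgS",
    "chromosomal replication initiator protein DnaA",
    "DNA-directed RNA polymerase subunit alpha RpoA",
    "DNA-directed RNA polymerase subunit beta RpoB",
    "DNA-directed RNA polymerase subunit beta' RpoC",
]


# ---------------------------------------------------------------------------
# configuration / truth containers
# ---------------------------------------------------------------------------

@dataclass
class TruthConfig:
    """Ground-truth configuration for the metagenome-side generators.

    Parameters
    ----------
    n_families : int
        Number of target metabolic gene families.
    n_uscg : int
        Number of universal single-copy control families (fold change
        fixed at 1 in every group).
    s_range : (int, int)
        Inclusive range of family size S (member genes per family).
    length_range : (int, int)
        Inclusive range of member protein lengths, in amino acids.
    baseline_range : (float, float)
        Per-family baseline concentration ``a`` is drawn log-uniformly
        from this interval (arbitrary concentration units).
    baseline_abundance : dict, optional
        Explicit per-family baselines overriding the random draw.
    fold_changes : dict
        ``{family_id: {group_or_role: fold}}`` positive multipliers
        applied to the baseline for samples of that group; lookup order
        is exact group label, then role (``control``/``disease``), then
        1.0.
    cohort_design : list
        ``(cohort, group, role, n_samples)`` tuples; 3-tuples
        ``(cohort, group, n)`` are accepted, the first-listed group of
        each cohort being treated as its control arm.  Defaults to the
        published three-cohort design (117/121, 72/14, 105/125).
    library_size_range : (int, int)
        Inclusive range of per-sample library sizes (total reads).
    divergence : float
        Per-site substitution probability used to derive family members
        from their reference sequence.
    subthreshold_rate, multihit_rate : float
        Noise rates in [0, 1]: fraction of true reads accompanied by an
        additional alignment row with E-value >= 1e-10 (must be removed
        by the E-value filter), and fraction of true reads carrying a
        strictly worse secondary hit (must be removed by best-hit
        filtering).
    n_spurious, n_fragments, n_divergent : int
        Decoy records added per family to the pangenome FASTA: near-miss
        annotations (for negative header matching), truncated members at
        40% of the reference length (for the length filter), and fully
        random sequences under the true annotation (for tree-based
        delimitation).
    overdispersion : float
        Optional Gamma-mixing coefficient for the hit counts; 0 keeps
        the pure Poisson model.
    seed : int
        Root seed for all generators.
    """

    n_families: int = 20
    n_uscg: int = 0
    s_range: tuple[int, int] = (1, 6)
    length_range: tuple[int, int] = (100, 500)
    baseline_range: tuple[float, float] = (0.5, 50.0)
    baseline_abundance: dict[str, float] | None = None
    fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    cohort_design: list[tuple] = field(default_factory=two_group_design)
    library_size_range: tuple[int, int] = (500_000, 2_000_000)
    divergence: float = 0.10
    subthreshold_rate: float = 0.05
    multihit_rate: float = 0.05
    n_spurious: int = 1
    n_fragments: int = 1
    n_divergent: int = 1
    overdispersion: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        for name in ("s_range", "length_range", "library_size_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a nonempty positive interval")
        lo, hi = self.baseline_range
        if lo <= 0 or hi < lo:
            raise ValueError("baseline_range must be a nonempty positive interval")
        if not self.cohort_design:
            raise ValueError("cohort_design must be nonempty")
        for entry in self.cohort_design:
            if entry[-1] <= 0:
                raise ValueError(f"cohort_design entry {entry!r} has no samples")
        for fam, folds in self.fold_changes.items():
            for g, f in folds.items():
                if not f > 0:
                    raise ValueError(f"fold change for {fam}/{g} must be > 0")
        for rate in (self.subthreshold_rate, self.multihit_rate):
            if not 0 <= rate <= 1:
                raise ValueError("noise rates must lie in [0, 1]")
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must lie in [0, 1)")


@dataclass
class SampleRecord:
    """One metagenomic sample: identity, comparison arm and library size."""

    sample_id: str
    cohort: str
    group: str
    role: str  # "control" or "disease" side of the cohort's comparison
    library_size: int
    fibrosis_stage: str | None = None


@dataclass
class FamilyTruth:
    """Generator-side truth for one gene family."""

    family_id: str
    product: str                    # header annotation shared by members
    member_ids: list[str]
    member_lengths_aa: dict[str, int]
    reference_id: str
    reference_seq: str
    baseline: float
    fold_changes: dict[str, float]
    pathway_tag: str = "target"     # "target" or "USCG"
    spurious_ids: list[str] = field(default_factory=list)
    fragment_ids: list[str] = field(default_factory=list)
    divergent_ids: list[str] = field(default_factory=list)

    @property
    def s(self) -> int:
        return len(self.member_ids)

    @property
    def mean_length_nt(self) -> float:
        return 3.0 * float(np.mean([self.member_lengths_aa[m] for m in self.member_ids]))

    def concentration(self, group: str, role: str) -> float:
        """True abundance a_fs for a sample of the given group/role."""
        fold = self.fold_changes.get(group, self.fold_changes.get(role, 1.0))
        return self.baseline * fold


# ---------------------------------------------------------------------------
# cohort design
# ---------------------------------------------------------------------------

def _normalize_design(design: list[tuple]) -> list[tuple[str, str, str, int]]:
    out, seen_cohorts = [], {}
    for entry in design:
        if len(entry) == 4:
            cohort, group, role, n = entry
        elif len(entry) == 3:
            cohort, group, n = entry
            role = "control" if cohort not in seen_cohorts else "disease"
        else:
            raise ValueError(f"cohort_design entry {entry!r} not understood")
        seen_cohorts.setdefault(cohort, group)
        out.append((cohort, group, role, int(n)))
    return out


def simulate_cohort_design(config: TruthConfig) -> list[SampleRecord]:
    """Draw one `SampleRecord` per sample of the configured design.

    Library sizes are uniform over ``library_size_range``; sample ids
    encode cohort and role.  Deterministic under the config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.library_size_range
    records = []
    for cohort, group, role, n in _normalize_design(config.cohort_design):
        libs = rng.integers(lo, hi + 1, size=n)
        for i in range(n):
            records.append(SampleRecord(
                sample_id=f"{cohort}_{role}_{i:04d}",
                cohort=cohort, group=group, role=role,
                library_size=int(libs[i]),
            ))
    return records


def samples_to_frame(samples: list[SampleRecord]) -> pd.DataFrame:
    """Tabulate sample records as the sample-metadata TSV shape."""
    return pd.DataFrame(
        [(s.sample_id, s.cohort, s.group, s.role, s.library_size,
          s.fibrosis_stage or "") for s in samples],
        columns=["sample_id", "cohort", "group", "role", "library_size",
                 "fibrosis_stage"],
    )


# ---------------------------------------------------------------------------
# pangenome FASTA with decoys
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AA_ALPHABET, size=length))

def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    if divergence == 0:
        return seq
    arr = np.array(list(seq))
    mask = rng.random(arr.size) < divergence
    if mask.any():
        # draw replacements until none equals the original residue
        repl = rng.choice(AA_ALPHABET, size=int(mask.sum()))
        orig = arr[mask]
        clash = repl == orig
        while clash.any():
            repl[clash] = rng.choice(AA_ALPHABET, size=int(clash.sum()))
            clash = repl == orig
        arr[mask] = repl
    return "".join(arr)


def simulate_gene_families(config: TruthConfig) -> tuple[str, list[FamilyTruth]]:
    """Generate an annotated pangenome FASTA plus per-family truth.

    Each family has S members derived from a random reference protein by
    point substitutions at ``config.divergence``.  Decoy records are
    interleaved to exercise the family builder: spurious near-miss
    annotations, sub-length fragments (40% of the reference) and fully
    random sequences carrying the true annotation.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    fasta = io.StringIO()
    truths: list[FamilyTruth] = []

    n_total = config.n_families + config.n_uscg
    baselines = np.exp(rng.uniform(np.log(config.baseline_range[0]),
                                   np.log(config.baseline_range[1]),
                                   size=n_total))
    for i in range(n_total):
        is_uscg = i >= config.n_families
        if is_uscg:
            k = i - config.n_families
            fam_id = f"uscg{k + 1:02d}"
            product = _USCG_PRODUCTS[k % len(_USCG_PRODUCTS)]
            if k >= len(_USCG_PRODUCTS):
                product += f" {k // len(_USCG_PRODUCTS) + 1}"
        else:
            fam_id = f"fam{i + 1:02d}"
            if i < len(_PRODUCT_NAMES):
                product = _PRODUCT_NAMES[i]
            else:
                # no product name may be a substring of another, so header
                # patterns isolate exactly one family
                product = f"putative metabolic enzyme {i + 1:03d}"

        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        s = int(rng.integers(config.s_range[0], config.s_range[1] + 1))
        ref_seq = _random_protein(rng, length)

        folds = dict(config.fold_changes.get(fam_id, {}))
        if is_uscg:
            folds = {}  # null by construction
        baseline = baselines[i]
        if config.baseline_abundance and fam_id in config.baseline_abundance:
            baseline = float(config.baseline_abundance[fam_id])

        truth = FamilyTruth(
            family_id=fam_id, product=product, member_ids=[],
            member_lengths_aa={}, reference_id=f"{fam_id}_ref",
            reference_seq=ref_seq, baseline=float(baseline),
            fold_changes=folds, pathway_tag="USCG" if is_uscg else "target",
        )
        for j in range(s):
            gid = f"{fam_id}_m{j + 1}"
            seq = _mutate(rng, ref_seq, config.divergence)
            truth.member_ids.append(gid)
            truth.member_lengths_aa[gid] = length
            fasta.write(f">{gid} {product}\n{seq}\n")
        for j in range(config.n_spurious):
            gid = f"{fam_id}_spur{j + 1}"
            truth.spurious_ids.append(gid)
            fasta.write(f">{gid} {product} 2\n{_random_protein(rng, length)}\n")
        for j in range(config.n_fragments):
            gid = f"{fam_id}_frag{j + 1}"
            truth.fragment_ids.append(gid)
            frag = _mutate(rng, ref_seq, config.divergence)[: max(1, int(0.4 * length))]
            fasta.write(f">{gid} {product}\n{frag}\n")
        for j in range(config.n_divergent):
            gid = f"{fam_id}_div{j + 1}"
            truth.divergent_ids.append(gid)
            fasta.write(f">{gid} {product}\n{_random_protein(rng, length)}\n")
        truths.append(truth)
    return fasta.getvalue(), truths


def family_metadata_frame(truths: list[FamilyTruth]) -> pd.DataFrame:
    """Family-metadata table (one row per member gene) for quantification."""
    rows = []
    for t in truths:
        for gid in t.member_ids:
            la = t.member_lengths_aa[gid]
            rows.append((t.family_id, gid, la, 3 * la, gid == t.reference_id,
                         t.pathway_tag))
    return pd.DataFrame(rows, columns=["family_id", "member_id", "length_aa",
                                       "length_nt", "is_reference", "pathway_tag"])


# ---------------------------------------------------------------------------
# per-sample alignment hit files (12-column tabular dialect)
# ---------------------------------------------------------------------------

ALIGNMENT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                     "gapopen", "qstart", "qend", "sstart", "send",
                     "evalue", "bitscore"]


def calibrate_baselines(
    truths: list[FamilyTruth],
    config: TruthConfig,
    min_reads: float = 500.0,
    spread: float = 2.0,
    rng: np.random.Generator | None = None,
) -> None:
    """Rescale family baselines so every family gets enough reads.

    Sets each family's baseline concentration to
    ``target * 1e6 / (S * Lbar_kb * lib_min)`` with ``target`` drawn
    log-uniformly from ``[min_reads, spread * min_reads]``, so the
    expected read count per family is at least ``min_reads`` in every
    sample.  This realises the regime where the RPKSM recovery contract
    is meaningful — rank agreement between RPKSM and truth cannot be
    expected for families whose Poisson counts are near zero.  Mutates
    the truth records in place.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    lib_min = config.library_size_range[0]
    for t in truths:
        target = float(np.exp(rng.uniform(np.log(min_reads),
                                          np.log(spread * min_reads))))
        t.baseline = target * 1e6 / (t.s * (t.mean_length_nt / 1000.0) * lib_min)


def true_abundance_matrix(truths: list[FamilyTruth],
                          samples: list[SampleRecord]) -> pd.DataFrame:
    """True concentration a_fs, families x samples."""
    data = {
        s.sample_id: [t.concentration(s.group, s.role) for t in truths]
        for s in samples
    }
    return pd.DataFrame(data, index=[t.family_id for t in truths])


def simulate_alignment_hits(
    config: TruthConfig,
    samples: list[SampleRecord],
    truths: list[FamilyTruth],
    outdir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate per-sample 12-column alignment tables.

    True reads for family *f* in sample *s* are Poisson with mean
    ``a_fs * S_f * Lbar_f(kb) * lib_s / 1e6`` and E-values < 1e-10,
    spread uniformly over member genes.  Noise rows are added at the
    configured rates: sub-threshold hits with E >= 1e-10 on fresh read
    ids, and strictly worse secondary hits on true reads.  If ``outdir``
    is given, one headerless TSV per sample (``<sample_id>.m8``) is
    written.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    all_genes = [g for t in truths for g in t.member_ids]
    out: dict[str, pd.DataFrame] = {}
    for s in samples:
        frames = []
        read_no = 0
        for t in truths:
            lam = (t.concentration(s.group, s.role) * t.s
                   * (t.mean_length_nt / 1000.0) * s.library_size / 1e6)
            if config.overdispersion > 0:
                shape = 1.0 / config.overdispersion
                lam = lam * rng.gamma(shape, 1.0 / shape)
            n = int(rng.poisson(lam)) if lam > 0 else 0
            if n == 0:
                continue
            genes = rng.choice(np.array(t.member_ids), size=n)
            lengths = np.array([t.member_lengths_aa[g] for g in genes])
            qlen = rng.integers(30, 81, size=n)
            evalue = 10.0 ** rng.uniform(-40, -15, size=n)
            frames.append(pd.DataFrame({
                "qseqid": [f"{s.sample_id}_r{read_no + k}" for k in range(n)],
                "sseqid": genes,
                "pident": np.round(rng.uniform(80, 100, size=n), 1),
                "length": qlen,
                "mismatch": rng.integers(0, 10, size=n),
                "gapopen": rng.integers(0, 2, size=n),
                "qstart": np.ones(n, dtype=int),
                "qend": qlen,
                "sstart": rng.integers(1, np.maximum(2, lengths - qlen)),
                "send": 0,  # filled below
                "evalue": evalue,
                "bitscore": np.round(rng.uniform(100, 300, size=n), 1),
            }))
            read_no += n
        if frames:
            df = pd.concat(frames, ignore_index=True)
            df["send"] = df["sstart"] + df["length"] - 1
        else:
            df = pd.DataFrame(columns=ALIGNMENT_COLUMNS)

        n_true = len(df)
        # secondary hits: strictly worse copies of true rows on other genes
        n_multi = int(round(config.multihit_rate * n_true))
        if n_multi > 0:
            idx = rng.choice(n_true, size=n_multi, replace=False)
            sec = df.iloc[idx].copy()
            sec["sseqid"] = rng.choice(np.array(all_genes), size=n_multi)
            sec["evalue"] = sec["evalue"].to_numpy() * 10.0 ** rng.uniform(1, 5, size=n_multi)
            sec["bitscore"] = np.round(
                sec["bitscore"].to_numpy() - rng.uniform(5, 50, size=n_multi), 1)
        else:
            sec = None
        # sub-threshold hits: fresh reads with E >= 1e-10
        n_sub = int(round(config.subthreshold_rate * n_true))
        if n_sub > 0:
            qlen = rng.integers(30, 81, size=n_sub)
            sub = pd.DataFrame({
                "qseqid": [f"{s.sample_id}_noise{k}" for k in range(n_sub)],
                "sseqid": rng.choice(np.array(all_genes), size=n_sub),
                "pident": np.round(rng.uniform(30, 60, size=n_sub), 1),
                "length": qlen,
                "mismatch": rng.integers(10, 30, size=n_sub),
                "gapopen": rng.integers(0, 4, size=n_sub),
                "qstart": np.ones(n_sub, dtype=int),
                "qend": qlen,
                "sstart": np.ones(n_sub, dtype=int),
                "send": qlen,
                "evalue": 10.0 ** rng.uniform(-9, 0, size=n_sub),
                "bitscore": np.round(rng.uniform(20, 50, size=n_sub), 1),
            })
        else:
            sub = None
        parts = [x for x in (df, sec, sub) if x is not None and len(x)]
        df = (pd.concat(parts, ignore_index=True) if parts
              else pd.DataFrame(columns=ALIGNMENT_COLUMNS))
        out[s.sample_id] = df
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            df.to_csv(outdir / f"{s.sample_id}.m8", sep="\t", header=False,
                      index=False, float_format="%.6g")
    return out


# ---------------------------------------------------------------------------
# taxon profile tables (MetaPhlAn-style)
# ---------------------------------------------------------------------------

_GENUS_POOL = [
    "Agathobacter", "Bacteroides", "Blautia", "Faecalibacterium",
    "Ruminococcus", "Gemmiger", "Streptococcus", "Mediterraneibacter",
    "Prevotella", "Roseburia", "Dorea", "Coprococcus", "Akkermansia",
    "Alistipes", "Fusicatenibacter", "Anaerostipes", "Lachnospira",
    "Oscillibacter", "Phocaeicola", "Parabacteroides", "Bifidobacterium",
    "Eubacterium", "Anaerobutyricum", "Flavonifractor",
]


@dataclass
class TaxaTruth:
    """Which synthetic clades play which role in the cleaning rules."""

    shared: list[str]                 # abundant in every cohort
    minor: list[str]                  # present everywhere, below threshold
    cohort_specific: dict[str, str]   # clade -> only cohort with signal
    group_exclusive: tuple[str, str, str]  # (clade, cohort, role)
    unclassified: str = "UNCLASSIFIED"


def _genus_lineage(name: str) -> str:
    return f"k__Bacteria|p__Synthetica|c__Clostridia|o__Lachnospirales|f__Lachnospiraceae|g__{name}"


def simulate_taxa_table(
    samples: list[SampleRecord],
    seed: int = 0,
    n_shared: int = 10,
    n_minor: int = 3,
    n_specific_per_cohort: int = 1,
    effects: dict[str, float] | None = None,
    concentration: float = 200.0,
) -> tuple[pd.DataFrame, TaxaTruth]:
    """Simulate a merged genus-level relative-abundance table (percent).

    Per sample, abundances follow a Dirichlet composition around fixed
    base proportions; ``effects`` maps genus name to a disease-group
    fold applied to the Dirichlet weight.  The table always contains an
    ``UNCLASSIFIED`` row, per-cohort-specific clades (zero outside one
    cohort), and one group-exclusive clade (nonzero only in one arm of
    one cohort), so every cleaning rule is exercised.  Columns sum to
    100 exactly.
    """
    if not samples:
        raise ValueError("sample list is empty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    effects = effects or {}
    cohorts = list(dict.fromkeys(s.cohort for s in samples))

    shared = _GENUS_POOL[:n_shared]
    minor = [f"Minorium_{chr(65 + i)}" for i in range(n_minor)]
    specific = {}
    for c in cohorts:
        for i in range(n_specific_per_cohort):
            specific[f"Cohortia_{c}_{i + 1}"] = c
    excl_clade, excl_cohort, excl_role = "Exclusivibacter", cohorts[0], "disease"
    names = (shared + minor + list(specific) + [excl_clade])

    # fixed base proportions: shared clades dominate, minors ~0.05%
    base = np.concatenate([
        2.0 / (1.0 + np.arange(n_shared)),          # shared, decreasing
        np.full(n_minor, 0.0008),                   # minor
        np.full(len(specific), 0.02),               # cohort-specific
        [0.01],                                     # group-exclusive
    ])
    unclassified_w = 0.08 * base.sum()

    cols = {}
    for s in samples:
        w = base.copy()
        if s.role == "disease":
            for i, name in enumerate(names):
                if name in effects:
                    w[i] *= effects[name]
        for i, name in enumerate(names):
            if name in specific and specific[name] != s.cohort:
                w[i] = 0.0
            if name == excl_clade and not (s.cohort == excl_cohort
                                           and s.role == excl_role):
                w[i] = 0.0
        w = np.append(w, unclassified_w)
        alpha = np.where(w > 0, concentration * w / w.sum(), 0.0)
        x = np.zeros_like(alpha)
        pos = alpha > 0
        x[pos] = rng.gamma(alpha[pos], 1.0)
        x = 100.0 * x / x.sum()
        cols[s.sample_id] = x

    index = [_genus_lineage(n) for n in names] + ["UNCLASSIFIED"]
    table = pd.DataFrame(cols, index=pd.Index(index, name="clade"))
    truth = TaxaTruth(shared=shared, minor=minor, cohort_specific=specific,
                      group_exclusive=(excl_clade, excl_cohort, excl_role))
    return table, truth


# ---------------------------------------------------------------------------
# genome / plasmid screen inputs
# ---------------------------------------------------------------------------

USCG_NAMES = ["argS", "dnaA", "rpoA", "rpoB", "rpoC"]


@dataclass
class CladeSpec:
    """One synthetic clade of genomes for the prevalence screen."""

    name: str            # UHGG-style genus label, e.g. "Ruminococcus_B"
    n_genomes: int       # genomes PASSING the completeness/USCG filter
    species: str | None = None


@dataclass
class ScreenTruthConfig:
    """Ground truth for the genome/plasmid presence screen.

    ``prevalence`` maps ``(clade_name, gene)`` to a carriage fraction in
    [0, 1]; the generator assigns exactly ``round(p * n_genomes)``
    carriers (a fixed-size random subset), so the configured prevalence
    is recovered sharply by a correct pipeline.  ``plasmid_counts`` maps
    gene to the exact number of curated plasmids carrying it.  Noise
    rates add scan hits that violate the coverage or E-value rules and
    genome/plasmid records that must be removed by the metadata filters.
    """

    clades: list[CladeSpec]
    prevalence: dict[tuple[str, str], float]
    plasmid_counts: dict[str, int] = field(default_factory=dict)
    profile_length_range: tuple[int, int] = (150, 600)
    failing_genome_fraction: float = 0.15
    false_hit_rate: float = 0.05
    partial_coverage_rate: float = 0.05
    n_excluded_plasmids: int = 6
    seed: int = 0

    def validate(self) -> None:
        if not self.clades:
            raise ValueError("clades must be nonempty")
        for c in self.clades:
            if c.n_genomes < 1:
                raise ValueError(f"clade {c.name} needs >= 1 genome")
        for key, p in self.prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {key} outside [0, 1]")
        for g, k in self.plasmid_counts.items():
            if k < 0:
                raise ValueError(f"plasmid count for {g} negative")


@dataclass
class ScreenInputs:
    """Bundle returned by `simulate_screen_inputs`."""

    genomes: pd.DataFrame       # genome metadata (completeness, USCG flags)
    plasmids: pd.DataFrame      # plasmid metadata (curation flags)
    scan_text: str              # per-domain scan table, domtblout dialect
    profile_lengths: dict[str, int]
    carriers: dict[tuple[str, str], list[str]]   # truth: (clade, gene) -> genomes
    plasmid_carriers: dict[str, list[str]]       # truth: gene -> curated plasmids


def _domtbl_line(target: str, tlen: int, query: str, qlen: int,
                 e_full: float, i_e: float, hmm_from: int, hmm_to: int,
                 score: float = 150.0) -> str:
    # HMMER3 domtblout column order (hmmscan: target = profile, query = ORF)
    return (f"{target} - {tlen} {query} - {qlen} "
            f"{e_full:.3g} {score:.1f} 0.1 1 1 "
            f"{e_full:.3g} {i_e:.3g} {score:.1f} 0.1 "
            f"{hmm_from} {hmm_to} 1 {hmm_to - hmm_from + 1} "
            f"1 {hmm_to - hmm_from + 3} 0.95 synthetic ORF\n")


def simulate_screen_inputs(config: ScreenTruthConfig,
                           genes: list[str] | None = None) -> ScreenInputs:
    """Generate genome/plasmid metadata plus a per-domain scan table.

    Passing genomes have completeness > 95 and all five USCGs; a stated
    extra fraction fail one of the two filters (and may still have scan
    hits, which a correct pipeline ignores).  Carrier hits satisfy all
    three hit filters; noise hits violate the E-value or coverage rule.
    Plasmid metadata includes partial, unassigned-host and internal-
    control records that curation must remove.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    if genes is None:
        genes = sorted({g for (_, g) in config.prevalence} | set(config.plasmid_counts))
    profile_lengths = {
        g: int(rng.integers(*config.profile_length_range)) for g in genes
    }

    # --- genomes -----------------------------------------------------------
    rows, genome_ids = [], {}
    orf_serial = {}
    for ci, clade in enumerate(config.clades):
        ids = [f"G{ci:02d}{i:05d}" for i in range(clade.n_genomes)]
        genome_ids[clade.name] = ids
        species = clade.species or f"{clade.name} sp001"
        for gid in ids:
            rows.append((gid, clade.name, species,
                         round(float(rng.uniform(95.2, 100.0)), 2),
                         *[True] * 5))
        n_fail = int(round(config.failing_genome_fraction * clade.n_genomes))
        for i in range(n_fail):
            gid = f"G{ci:02d}F{i:04d}"
            if i % 2 == 0:   # incomplete
                rows.append((gid, clade.name, species,
                             round(float(rng.uniform(70.0, 95.0)), 2),
                             *[True] * 5))
            else:            # missing one USCG
                flags = [True] * 5
                flags[int(rng.integers(5))] = False
                rows.append((gid, clade.name, species,
                             round(float(rng.uniform(95.2, 100.0)), 2), *flags))
    genomes = pd.DataFrame(
        rows, columns=["genome_id", "genus", "species", "completeness",
                       *[f"uscg_{n}" for n in USCG_NAMES]])

    # --- scan hits on genomes ---------------------------------------------
    lines = ["# synthetic per-domain scan table\n"]
    carriers: dict[tuple[str, str], list[str]] = {}

    def _orf(replicon: str) -> str:
        orf_serial[replicon] = orf_serial.get(replicon, 0) + 1
        return f"{replicon}_{orf_serial[replicon]}"

    def _passing_hit(replicon: str, gene: str) -> str:
        plen = profile_lengths[gene]
        start = int(rng.integers(1, 4))
        span = int(np.ceil(0.93 * plen)) + int(rng.integers(0, max(1, int(0.04 * plen))))
        end = min(plen, start + span - 1)
        e = 10.0 ** rng.uniform(-40, -5)
        return _domtbl_line(gene, plen, _orf(replicon), int(rng.integers(200, 700)),
                            e, e * 10.0 ** rng.uniform(0, 1.5), start, end)

    n_passing_hits = 0
    for clade in config.clades:
        ids = np.array(genome_ids[clade.name])
        for gene in genes:
            p = config.prevalence.get((clade.name, gene), 0.0)
            n_carry = int(round(p * clade.n_genomes))
            chosen = rng.choice(ids, size=n_carry, replace=False) if n_carry else []
            carriers[(clade.name, gene)] = sorted(map(str, chosen))
            for gid in carriers[(clade.name, gene)]:
                lines.append(_passing_hit(gid, gene))
                n_passing_hits += 1

    all_genome_ids = genomes["genome_id"].to_numpy()
    n_false = int(round(config.false_hit_rate * max(n_passing_hits, 1)))
    for _ in range(n_false):
        gene = genes[int(rng.integers(len(genes)))]
        plen = profile_lengths[gene]
        gid = str(rng.choice(all_genome_ids))
        e = float(rng.uniform(0.02, 5.0))   # fails E < 0.01
        lines.append(_domtbl_line(gene, plen, _orf(gid),
                                  int(rng.integers(200, 700)),
                                  e, e, 1, plen))
    n_partial = int(round(config.partial_coverage_rate * max(n_passing_hits, 1)))
    for _ in range(n_partial):
        gene = genes[int(rng.integers(len(genes)))]
        plen = profile_lengths[gene]
        gid = str(rng.choice(all_genome_ids))
        end = max(2, int(0.60 * plen))      # coverage <= 0.90
        e = 10.0 ** rng.uniform(-30, -5)
        lines.append(_domtbl_line(gene, plen, _orf(gid),
                                  int(rng.integers(200, 700)),
                                  e, e * 2, 1, end))

    # --- plasmids ----------------------------------------------------------
    prows, plasmid_carriers = [], {}
    serial = 0
    hosts = [c.species or f"{c.name} sp001" for c in config.clades]
    for gene in genes:
        k = config.plasmid_counts.get(gene, 0)
        plasmid_carriers[gene] = []
        for _ in range(k):
            pid = f"P{serial:05d}"; serial += 1
            prows.append((pid, hosts[int(rng.integers(len(hosts)))], False, False))
            plasmid_carriers[gene].append(pid)
            lines.append(_passing_hit(pid, gene))
    # excluded plasmids, each carrying a passing hit curation must discard
    for i in range(config.n_excluded_plasmids):
        pid = f"P{serial:05d}"; serial += 1
        kind = i % 3
        prows.append((pid,
                      "unassigned" if kind == 0 else hosts[0],
                      kind == 1, kind == 2))
        gene = genes[int(rng.integers(len(genes)))]
        lines.append(_passing_hit(pid, gene))
    # curated plasmids with no candidate-gene cargo
    for _ in range(4):
        pid = f"P{serial:05d}"; serial += 1
        prows.append((pid, hosts[int(rng.integers(len(hosts)))], False, False))
    plasmids = pd.DataFrame(
        prows, columns=["plasmid_id", "host_assignment", "partial_flag",
                        "control_flag"])

    return ScreenInputs(genomes=genomes, plasmids=plasmids,
                        scan_text="".join(lines),
                        profile_lengths=profile_lengths,
                        carriers=carriers, plasmid_carriers=plasmid_carriers)
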