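"""Seeded generators for every input the pipeline consumes.

The real training resource — a curated table of splice-altering and benign
variants with wild-type/mutant splice-site scores from several tools — is
licensed and cannot be redistributed, so this module emulates its
*statistical shape*: a labeled feature table whose per-feature class
separability is calibrated to stated single-feature AUC targets, with the
published class sizes (1164 positive / 1795 negative) as defaults.

Features are class-conditional Gaussians sharing a latent factor: the seven
score variations of one variant are measurements of the same underlying
splicing disruption, so they are positively correlated within class.  For a
positive-class mean shift delta and common within-class s.d. sigma, the
single-feature AUC has the closed form  AUC = Phi(delta / (sigma * sqrt(2))),
which is inverted to calibrate delta per feature.  Per-feature missing
rates emulate wild-type-score-zero failures.

What this does not emulate: real score distributions are bounded, skewed
and tool-specific, missingness correlates with weak splice sites, and the
ensemble-vs-single improvement depends on how complementary real tools are.
Passing tests on this generator therefore validates the machinery and the
qualitative orderings, not the published performance numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .regions import RegionDefinition, region_for
from .variation import EXTRA_NAMES, FEATURE_NAMES_7, FeatureRow

#: Single-feature AUC targets for the seven score variations
#: (pwm_rel, pwm_abs, mes_rel, nnsplice_rel, nnsplice_abs, hsf_rel, hsf_abs).
DEFAULT_TARGET_AUCS_7 = (0.95, 0.95, 0.94, 0.90, 0.91, 0.93, 0.93)
#: AUC target for each of the four conservation/functional extras.
DEFAULT_TARGET_AUC_EXTRA = 0.80
#: Missing rates for the seven variations (tool failure to see the wild-type
#: site); extras are near-complete.
DEFAULT_MISSING_RATES_7 = (0.026, 0.026, 0.028, 0.023, 0.023, 0.022, 0.022)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic labeled feature table."""

    seed: int = 0
    n_pos: int = 1164
    n_neg: int = 1795
    n_features: int = 7  # 7 or 11
    target_aucs: tuple = DEFAULT_TARGET_AUCS_7
    extra_auc: float = DEFAULT_TARGET_AUC_EXTRA
    sd: float = 1.0
    rho: float = 0.5  # within-class shared-factor correlation
    missing_rates: tuple = DEFAULT_MISSING_RATES_7
    extra_missing_rate: float = 0.0

    def __post_init__(self):
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise ValueError("class sizes must be positive")
        if self.n_features not in (7, 11):
            raise ValueError("n_features must be 7 or 11")
        aucs = self.all_target_aucs
        if any(not 0.5 < a < 1.0 for a in aucs):
            raise ValueError("target AUCs must lie strictly in (0.5, 1)")
        if any(not 0.0 <= m < 1.0 for m in self.all_missing_rates):
            raise ValueError("missing rates must lie in [0, 1)")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")

    @property
    def all_target_aucs(self) -> tuple:
        if self.n_features == 7:
            return tuple(self.target_aucs)
        return tuple(self.target_aucs) + (self.extra_auc,) * 4

    @property
    def all_missing_rates(self) -> tuple:
        if self.n_features == 7:
            return tuple(self.missing_rates)
        return tuple(self.missing_rates) + (self.extra_missing_rate,) * 4

    @property
    def deltas(self) -> np.ndarray:
        """Positive-class mean shifts solving AUC = Phi(delta/(sd*sqrt(2)))."""
        a = np.asarray(self.all_target_aucs)
        return norm.ppf(a) * self.sd * np.sqrt(2.0)


def gen_feature_table(spec: SyntheticSpec) -> list:
    """Labeled FeatureRow table calibrated to the spec's AUC targets."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    p = spec.n_features
    y = np.concatenate([np.ones(spec.n_pos, int), np.zeros(spec.n_neg, int)])
    # shared latent factor induces within-class correlation rho
    latent = rng.standard_normal(n)[:, None] * np.sqrt(spec.rho)
    noise = rng.standard_normal((n, p)) * np.sqrt(1.0 - spec.rho)
    X = (latent + noise) * spec.sd + y[:, None] * spec.deltas[None, :]
    for j, rate in enumerate(spec.all_missing_rates):
        if rate > 0:
            X[rng.random(n) < rate, j] = np.nan
    order = rng.permutation(n)
    X, y = X[order], y[order]
    return [
        FeatureRow(id=f"sv{i:05d}", features=X[i], label=int(y[i]))
        for i in range(n)
    ]


def table_manifest(rows) -> dict:
    """Realized class sizes, per-feature missing rates and single-feature AUCs."""
    from .evaluate import roc_auc

    X = np.vstack([r.features for r in rows])
    y = np.array([r.label for r in rows])
    names = FEATURE_NAMES_7 if X.shape[1] == 7 else FEATURE_NAMES_7 + EXTRA_NAMES
    aucs, missing = {}, {}
    for j, name in enumerate(names):
        ok = np.isfinite(X[:, j])
        missing[name] = float((~ok).mean())
        aucs[name] = roc_auc(X[ok, j], y[ok]).auc if np.unique(y[ok]).size == 2 else None
    return {
        "n_pos": int((y == 1).sum()),
        "n_neg": int((y == 0).sum()),
        "missing_rates": missing,
        "single_feature_aucs": aucs,
    }


#: Consensus bases of the canonical donor and acceptor windows.  The donor
#: exon end is MAG | GTRAGT-like; we use the modal human bases.
DONOR_CONSENSUS = "CAGGTAAGTAT"  # offsets -3..+8
ACCEPTOR_CONSENSUS = "TTTTTTTTTCAGGT"  # offsets -12..+2

_PURINE = {"R": "AG", "Y": "CT"}


def gen_splice_sites(
    region: RegionDefinition | str,
    consensus_strength: float = 0.9,
    n: int = 100,
    seed: int = 0,
) -> list:
    """Sample splice-site window sequences around the canonical consensus.

    The invariant GT/AG dinucleotide is fixed; every other position draws
    the consensus base with probability ``strength + (1-strength)/4`` and
    each other base uniformly otherwise, so strength 1 reproduces the
    consensus exactly and strength 0 is uniform outside GT/AG.
    """
    if isinstance(region, str):
        region = region_for(region)
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= consensus_strength <= 1.0:
        raise ValueError("consensus_strength must lie in [0, 1]")
    consensus = DONOR_CONSENSUS if region.site_kind == "donor" else ACCEPTOR_CONSENSUS
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs = []
    for _ in range(n):
        chars = []
        for off, cons in zip(region.offsets, consensus):
            if off in region.invariant_offsets:
                chars.append(cons)
            elif rng.random() < consensus_strength:
                chars.append(cons)
            else:
                chars.append(str(rng.choice(bases)))
        seqs.append("".join(chars))
    return seqs


@dataclass
class ToyGenomeSpec:
    seed: int = 0
    n_genes: int = 2
    exons_per_gene: int = 3
    exon_length: int = 60
    intron_length: int = 120
    flank: int = 200
    minus_strand_fraction: float = 0.5

    def __post_init__(self):
        if self.intron_length < 30:
            raise ValueError(
                "introns shorter than 30 nt would overlap donor/acceptor windows"
            )
        if self.exon_length < 15:
            raise ValueError("exons must cover the exonic window spans")


def gen_toy_genome(spec: ToyGenomeSpec) -> tuple:
    """Random single-chromosome genome with planted multi-exon genes.

    Returns (fasta_text, gtf_text).  Intron ends carry the canonical GT/AG
    in each gene's transcription orientation; genes alternate strands up to
    ``minus_strand_fraction``.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    gene_span = (
        spec.exons_per_gene * spec.exon_length
        + (spec.exons_per_gene - 1) * spec.intron_length
    )
    total = spec.flank + spec.n_genes * (gene_span + spec.flank)
    seq = list(rng.choice(list("ACGT"), size=total))
    gtf_lines = []
    chrom = "chrT"
    cursor = spec.flank
    for g in range(spec.n_genes):
        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
        exons = []
        start = cursor + 1  # 1-based
        for e in range(spec.exons_per_gene):
            s = start + e * (spec.exon_length + spec.intron_length)
            exons.append((s, s + spec.exon_length - 1))
        # plant GT..AG at each intron in transcription orientation
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            istart, iend = e1 + 1, s2 - 1
            if strand == "+":
                seq[istart - 1], seq[istart] = "G", "T"
                seq[iend - 2], seq[iend - 1] = "A", "G"
            else:
                # transcription runs high->low: GT at the high end, AG low
                seq[iend - 1], seq[iend - 2] = "C", "A"  # + strand "AC" = GT rc
                seq[istart], seq[istart - 1] = "T", "C"  # + strand "CT" = AG rc
        gene_id, tx_id = f"gene{g + 1}", f"tx{g + 1}"
        tx_exons = exons if strand == "+" else exons[::-1]
        for s, e in tx_exons:
            gtf_lines.append(
                f"{chrom}\ttoy\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
            )
        cursor += gene_span + spec.flank
    fasta = f">{chrom}\n" + "".join(seq) + "\n"
    return fasta, "\n".join(gtf_lines) + "\n"


#: Splice-altering proportions per recurrence bin used as generator defaults
#: (once-or-twice, three-or-four, five-plus).
DEFAULT_RECURRENCE_PROPORTIONS = (0.707, 0.742, 0.845)
DEFAULT_RECURRENCE_TOTALS = (4000, 300, 130)


@dataclass
class RecurrenceSpec:
    totals: tuple = DEFAULT_RECURRENCE_TOTALS
    proportions: tuple = DEFAULT_RECURRENCE_PROPORTIONS

    def __post_init__(self):
        if any(not 0.0 <= p <= 1.0 for p in self.proportions):
            raise ValueError("proportions must lie in [0, 1]")
        if len(self.totals) != len(self.proportions):
            raise ValueError("totals and proportions must align")


def gen_recurrence(spec: RecurrenceSpec = RecurrenceSpec(), seed: int = 0) -> list:
    """(recurrence_count, is_positive) draws at the configured proportions.

    Recurrence values are drawn uniformly inside each bin's range (1-2, 3-4,
    5-8); bins with zero total contribute nothing.
    """
    rng = np.random.default_rng(seed)
    ranges = ((1, 2), (3, 4), (5, 8))
    out = []
    for (lo, hi), n, p in zip(ranges, spec.totals, spec.proportions):
        for _ in range(int(n)):
            rec = int(rng.integers(lo, hi + 1))
            out.append((rec, bool(rng.random() < p)))
    return out
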