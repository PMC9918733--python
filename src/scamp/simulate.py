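"""Clone-structured synthetic data generator for targeted single-cell DNA-seq.

Emulates the statistical structure of droplet-based targeted amplicon
sequencing of tumor nuclei: a small number of clones with defined SNV
genotypes and per-amplicon copy-number profiles, overdispersed per-amplicon
read depth, symmetric per-allele dropout at heterozygous sites, cross-clone
doublets formed by summing two nuclei's reads, and low-depth background
barcodes that carry no genotype signal.

Model summary
-------------
Per real cell, each amplicon's read count is negative binomial with mean
``mean_depth × efficiency × copy_number / 2`` and a configurable dispersion.
Each variant maps to exactly one covering amplicon and inherits that
amplicon's reads as its total depth DP. The alternate-read count AD is
binomial in DP with success probability 0 (WT), 0.5 (HET) or 1 (HOM); at HET
sites each of the two alleles drops out independently with probability ``q``
(ref dropped → expected VAF 1, alt dropped → 0, both dropped → DP forced to 0
so the site is unobservable). Doublets occur with probability ``d`` and are
the elementwise sum of two independently drawn cells' count vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    AmpliconMatrix,
    AmpliconPanel,
    CellVariantData,
    ConfigError,
    Genotype,
    VariantId,
)

__all__ = [
    "CloneSpec",
    "SimConfig",
    "SimTruth",
    "default_panel",
    "simulate_dataset",
    "simulate_mixing_experiment",
    "simulate_het_snp_reads",
    "mixing_categories",
]

# Genes recurrently altered in pancreatic ductal adenocarcinoma; the default
# panel tiles amplicons over them with extra coverage for the recurrently
# deleted tumor suppressors.
_PDAC_GENES = [
    "KRAS", "TP53", "ARID1A", "TGFBR2", "FGFR1", "RREB1",
    "GNAS", "RNF43", "MYC", "BRCA2", "ATM", "MAP2K4", "ACVR1B", "STK11",
]


def default_panel(n_amplicons: int = 186) -> AmpliconPanel:
    """A PDAC-like targeted panel of ``n_amplicons`` amplicons.

    Amplicons are ~200 bp intervals assigned round-robin over a set of
    recurrently altered genes, with SMAD4 and CDKN2A receiving a contiguous
    block of 8 amplicons each so that focal homozygous deletions span
    several panel columns, as they do on real panels.
    """
    rows = []
    gene_cycle: list[str] = []
    for g in ("SMAD4", "CDKN2A"):
        gene_cycle.extend([g] * 8)
    i = 0
    while len(gene_cycle) < n_amplicons:
        gene_cycle.append(_PDAC_GENES[i % len(_PDAC_GENES)])
        i += 1
    gene_counter: dict[str, int] = {}
    for k, gene in enumerate(gene_cycle[:n_amplicons]):
        gene_counter[gene] = gene_counter.get(gene, 0) + 1
        chrom = str((hash(gene) % 22) + 1)
        start = 1_000_000 + k * 10_000
        rows.append(
            {
                "amplicon_id": f"AMPL_{gene}_{gene_counter[gene]}",
                "chrom": chrom,
                "start": start,
                "end": start + 199,
                "gene": gene,
            }
        )
    return AmpliconPanel(pd.DataFrame(rows))


@dataclass
class CloneSpec:
    """One clone: its population proportion, SNV genotype and CNV profile.

    ``genotype`` maps variants to {WT, HET, HOM}; unlisted variants are WT.
    ``copy_number`` maps amplicon ids to copies (2 = diploid, 1 = single-copy
    loss, 0 = homozygous deletion); unlisted amplicons are diploid.
    """

    clone_id: str
    proportion: float
    genotype: dict[VariantId, Genotype] = field(default_factory=dict)
    copy_number: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(cn < 0 for cn in self.copy_number.values()):
            raise ConfigError(f"clone {self.clone_id}: negative copy number")
        if any(g == Genotype.MISSING for g in self.genotype.values()):
            raise ConfigError(f"clone {self.clone_id}: MISSING is not a true genotype")


@dataclass
class SimConfig:
    """Full specification of a simulated library.

    Defaults reflect a typical solid-tumor nuclei run on a ~186-amplicon
    panel: target mean depth 100 reads/cell/amplicon, droplet doublet rate
    4% (middle of the 3-5% range genotype mixing experiments estimate for
    this kind of workflow), per-allele dropout 0.1101 (so ~19.6% of HET
    observations lose exactly one allele), and a population of low-depth
    background barcodes at 5% of cell depth.
    """

    panel: AmpliconPanel
    variants: list[VariantId]
    clones: list[CloneSpec]
    n_cells: int = 1000
    doublet_rate: float = 0.04
    ado_prob: float = 0.1101
    mean_depth_per_amplicon: float = 100.0
    depth_dispersion: float = 10.0
    amplicon_efficiency: dict[str, float] = field(default_factory=dict)
    n_background_barcodes: int = 1000
    background_depth_scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.doublet_rate < 1.0):
            raise ConfigError(f"doublet_rate {self.doublet_rate} outside [0,1)")
        if not (0.0 <= self.ado_prob < 1.0):
            raise ConfigError(f"ado_prob {self.ado_prob} outside [0,1)")
        if self.n_cells <= 0:
            raise ConfigError("n_cells must be positive")
        if self.mean_depth_per_amplicon <= 0 or self.depth_dispersion <= 0:
            raise ConfigError("depth parameters must be positive")
        total = sum(c.proportion for c in self.clones)
        if not self.clones or abs(total - 1.0) > 1e-9:
            raise ConfigError(f"clone proportions sum to {total}, expected 1")
        amplicon_ids = set(self.panel.amplicon_ids)
        for v in self.variants:
            if self.panel.covering_amplicon(v) is None:
                raise ConfigError(f"variant {v} not covered by any amplicon")
        for c in self.clones:
            for v in c.genotype:
                if v not in self.variants:
                    raise ConfigError(f"clone {c.clone_id} genotype names unknown variant {v}")
            for a in c.copy_number:
                if a not in amplicon_ids:
                    raise ConfigError(f"clone {c.clone_id} names unknown amplicon {a!r}")


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator, aligned to output barcodes.

    ``clone_labels[i]`` is a clone id for singlets, an ordered pair of clone
    ids for doublets, and ``None`` for background barcodes. True genotypes for
    doublets are the carrier union (elementwise max) of the constituents;
    true copy numbers the constituent mean. ``dropout`` codes per cell-variant:
    0 none, 1 ref allele dropped, 2 alt dropped, 3 both dropped (HET singlet
    sites only; 0 elsewhere). ``doublet_components`` keeps each doublet's two
    constituent amplicon count vectors (conservation: their sum is the
    emitted row).
    """

    barcodes: list[str]
    clone_labels: list[object]
    is_doublet: np.ndarray
    is_background: np.ndarray
    genotypes: np.ndarray  # (n_barcodes, n_variants) int8
    copy_numbers: np.ndarray  # (n_barcodes, n_amplicons) float
    dropout: np.ndarray  # (n_barcodes, n_variants) int8
    doublet_components: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def doublet_fraction(self) -> float:
        """Observed doublet fraction among cell (non-background) barcodes."""
        cells = ~self.is_background
        return float(self.is_doublet[cells].mean())

    def clone_proportions(self) -> dict[str, float]:
        """Singlet clone label frequencies (doublets/background excluded)."""
        mask = ~self.is_background & ~self.is_doublet
        labels = [self.clone_labels[i] for i in np.flatnonzero(mask)]
        out: dict[str, float] = {}
        for lab in labels:
            out[lab] = out.get(lab, 0) + 1
        return {k: v / len(labels) for k, v in out.items()}


def _nbinom(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial draws with the (mean, size) parameterization.

    var = mean + mean^2/dispersion. Zero means yield zero counts exactly.
    """
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = dispersion / (dispersion + mean[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def _het_dropout_codes(rng: np.random.Generator, shape: tuple[int, ...], q: float) -> np.ndarray:
    """Per-site allele-dropout codes: 0 none, 1 ref, 2 alt, 3 both."""
    drop_ref = rng.random(shape) < q
    drop_alt = rng.random(shape) < q
    return (drop_ref.astype(np.int8) + 2 * drop_alt.astype(np.int8)).astype(np.int8)


_HET_ALT_FRACTION = np.array([0.5, 1.0, 0.0, 0.0])  # indexed by dropout code


def simulate_dataset(config: SimConfig) -> tuple[CellVariantData, AmpliconMatrix, SimTruth]:
    """Simulate one library: cells, doublets and background barcodes.

    Returns the cell×variant DP/AD matrices, the barcode×amplicon count
    matrix (same barcodes, panel order) and the ground truth. Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    amplicons = panel.amplicon_ids
    n_amp = len(amplicons)
    n_var = len(config.variants)
    amp_index = {a: k for k, a in enumerate(amplicons)}
    var_amp = np.array(
        [amp_index[panel.covering_amplicon(v)] for v in config.variants], dtype=np.intp
    )

    k_clones = len(config.clones)
    proportions = np.array([c.proportion for c in config.clones], dtype=float)
    # clone-level genotype (k×V) and copy-number (k×A) matrices
    clone_gt = np.zeros((k_clones, n_var), dtype=np.int8)
    clone_cn = np.full((k_clones, n_amp), 2.0)
    for z, clone in enumerate(config.clones):
        for v, g in clone.genotype.items():
            clone_gt[z, config.variants.index(v)] = np.int8(g)
        for a, cn in clone.copy_number.items():
            clone_cn[z, amp_index[a]] = cn
    efficiency = np.array([config.amplicon_efficiency.get(a, 1.0) for a in amplicons])

    n_cells = config.n_cells
    is_doublet = rng.random(n_cells) < config.doublet_rate
    n_const = n_cells + int(is_doublet.sum())
    const_clone = rng.choice(k_clones, size=n_const, p=proportions)
    # constituent k of barcode i: owner[i] lists constituent row indices
    second = np.full(n_cells, -1, dtype=np.intp)
    second[is_doublet] = n_cells + np.arange(int(is_doublet.sum()))

    mean_depth = config.mean_depth_per_amplicon
    means = mean_depth * efficiency[None, :] * clone_cn[const_clone] / 2.0
    const_counts = _nbinom(rng, means, config.depth_dispersion)

    const_dp = const_counts[:, var_amp]
    const_gt = clone_gt[const_clone]
    # dropout only matters at HET sites; both-dropped HET sites are unobservable
    codes = _het_dropout_codes(rng, const_gt.shape, config.ado_prob)
    codes[const_gt != Genotype.HET] = 0
    het = const_gt == Genotype.HET
    const_dp = const_dp.copy()
    const_dp[het & (codes == 3)] = 0
    frac = np.zeros(const_gt.shape)
    frac[const_gt == Genotype.HOM] = 1.0
    frac[het] = _HET_ALT_FRACTION[codes[het]]
    const_ad = rng.binomial(const_dp, frac)

    # assemble barcodes: singlets pass through, doublets sum two constituents
    cell_barcodes = [f"cell{i:05d}" for i in range(n_cells)]
    counts = const_counts[:n_cells].copy()
    dp = const_dp[:n_cells].copy()
    ad = const_ad[:n_cells].copy()
    genotypes = const_gt[:n_cells].copy()
    copy_numbers = clone_cn[const_clone[:n_cells]].copy()
    dropout = codes[:n_cells].copy()
    clone_ids = [config.clones[z].clone_id for z in const_clone]
    labels: list[object] = list(clone_ids[:n_cells])
    components: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for i in np.flatnonzero(is_doublet):
        j = second[i]
        components[cell_barcodes[i]] = (const_counts[i].copy(), const_counts[j].copy())
        counts[i] = const_counts[i] + const_counts[j]
        dp[i] = const_dp[i] + const_dp[j]
        ad[i] = const_ad[i] + const_ad[j]
        genotypes[i] = np.maximum(const_gt[i], const_gt[j])
        copy_numbers[i] = (clone_cn[const_clone[i]] + clone_cn[const_clone[j]]) / 2.0
        dropout[i] = 0
        labels[i] = (clone_ids[i], clone_ids[j])

    # background barcodes: scaled-down depth, no genotype signal
    n_bg = config.n_background_barcodes
    if n_bg > 0:
        bg_means = np.broadcast_to(
            mean_depth * efficiency * config.background_depth_scale, (n_bg, n_amp)
        )
        bg_counts = _nbinom(rng, bg_means, config.depth_dispersion)
        bg_dp = bg_counts[:, var_amp]
        bg_ad = rng.binomial(bg_dp, rng.random((n_bg, n_var)))
        counts = np.vstack([counts, bg_counts])
        dp = np.vstack([dp, bg_dp])
        ad = np.vstack([ad, bg_ad])
        genotypes = np.vstack([genotypes, np.full((n_bg, n_var), np.int8(Genotype.MISSING))])
        copy_numbers = np.vstack([copy_numbers, np.full((n_bg, n_amp), np.nan)])
        dropout = np.vstack([dropout, np.zeros((n_bg, n_var), dtype=np.int8)])
        labels.extend([None] * n_bg)
    barcodes = cell_barcodes + [f"bg{i:05d}" for i in range(n_bg)]

    data = CellVariantData(barcodes=barcodes, variants=list(config.variants), DP=dp, AD=ad)
    amp_matrix = AmpliconMatrix(barcodes=barcodes, amplicons=amplicons, counts=counts)
    truth = SimTruth(
        barcodes=barcodes,
        clone_labels=labels,
        is_doublet=np.concatenate([is_doublet, np.zeros(n_bg, dtype=bool)]),
        is_background=np.concatenate([np.zeros(n_cells, dtype=bool), np.ones(n_bg, dtype=bool)]),
        genotypes=genotypes,
        copy_numbers=copy_numbers,
        dropout=dropout,
        doublet_components=components,
    )
    return data, amp_matrix, truth


# Private driver variants used by the two-population mixing experiment,
# emulating a TP53 missense vs an ARID1A splice variant from two patients.
MIXING_DRIVER_A = VariantId(chrom="17", pos=7578190, ref="G", alt="A")
MIXING_DRIVER_B = VariantId(chrom="1", pos=27106355, ref="C", alt="T")


def _mixing_panel() -> AmpliconPanel:
    return AmpliconPanel(
        pd.DataFrame(
            [
                {"amplicon_id": "AMPL_TP53_mix", "chrom": "17", "start": 7578100, "end": 7578299, "gene": "TP53"},
                {"amplicon_id": "AMPL_ARID1A_mix", "chrom": "1", "start": 27106300, "end": 27106499, "gene": "ARID1A"},
                {"amplicon_id": "AMPL_KRAS_mix", "chrom": "12", "start": 25398200, "end": 25398399, "gene": "KRAS"},
                {"amplicon_id": "AMPL_GNAS_mix", "chrom": "20", "start": 57484400, "end": 57484599, "gene": "GNAS"},
            ]
        )
    )


def simulate_mixing_experiment(
    p: float,
    d: float,
    n_droplets: int,
    seed: int,
    ado_q: float = 0.0,
    mean_depth: float = 300.0,
    depth_dispersion: float = 300.0,
) -> tuple[CellVariantData, SimTruth]:
    """Two-population nuclei mixing run for doublet-rate estimation.

    Two tumor populations, A (proportion ``p``) and B, each carry one private
    heterozygous driver. Each droplet is a doublet with probability ``d``;
    doublet constituents are drawn independently from the mixed suspension, so
    cross-population (AB) droplets arise at rate ``2 d p (1-p)``. Fully
    vectorized; deterministic given ``seed``.

    Default depth parameters emulate a deeply sequenced mixing run (about 300
    reads/cell/amplicon, modest overdispersion): a cross-population doublet's
    expected VAF at each driver is 0.25, only five points above the 20%
    wildtype bin, so the genotype classification is only reliable when
    within-droplet read depth is deep and balanced between the two nuclei.
    """
    if not (0.0 < p < 1.0):
        raise ConfigError(f"population fraction p={p} outside (0,1)")
    if not (0.0 <= d < 1.0):
        raise ConfigError(f"doublet rate d={d} outside [0,1)")
    if n_droplets <= 0:
        raise ConfigError("n_droplets must be positive")
    rng = np.random.default_rng(seed)
    panel = _mixing_panel()
    variants = [MIXING_DRIVER_A, MIXING_DRIVER_B]
    n_amp = len(panel)
    var_amp = np.array([0, 1], dtype=np.intp)

    is_doublet = rng.random(n_droplets) < d
    # constituent population: True = A. Layer 2 only active for doublets.
    pop1 = rng.random(n_droplets) < p
    pop2 = rng.random(n_droplets) < p

    def layer(pop: np.ndarray, active: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        means = np.where(active[:, None], mean_depth, 0.0) * np.ones((1, n_amp))
        counts = _nbinom(rng, means, depth_dispersion)
        dp = counts[:, var_amp].copy()
        # HET at the private driver of the constituent's own population
        het = np.zeros((n_droplets, 2), dtype=bool)
        het[:, 0] = pop
        het[:, 1] = ~pop
        codes = _het_dropout_codes(rng, het.shape, ado_q)
        codes[~het] = 0
        dp[het & (codes == 3)] = 0
        frac = np.zeros((n_droplets, 2))
        frac[het] = _HET_ALT_FRACTION[codes[het]]
        ad = rng.binomial(dp, frac)
        return counts, dp, ad

    c1, dp1, ad1 = layer(pop1, np.ones(n_droplets, dtype=bool))
    c2, dp2, ad2 = layer(pop2, is_doublet)
    counts = c1 + c2
    dp = dp1 + dp2
    ad = ad1 + ad2

    barcodes = [f"drop{i:05d}" for i in range(n_droplets)]
    lab1 = np.where(pop1, "A", "B")
    lab2 = np.where(pop2, "A", "B")
    labels: list[object] = [
        (str(lab1[i]), str(lab2[i])) if is_doublet[i] else str(lab1[i])
        for i in range(n_droplets)
    ]
    genotypes = np.zeros((n_droplets, 2), dtype=np.int8)
    carrier_a = pop1 | (is_doublet & pop2)
    carrier_b = (~pop1) | (is_doublet & ~pop2)
    genotypes[carrier_a, 0] = np.int8(Genotype.HET)
    genotypes[carrier_b, 1] = np.int8(Genotype.HET)
    truth = SimTruth(
        barcodes=barcodes,
        clone_labels=labels,
        is_doublet=is_doublet,
        is_background=np.zeros(n_droplets, dtype=bool),
        genotypes=genotypes,
        copy_numbers=np.full((n_droplets, n_amp), 2.0),
        dropout=np.zeros((n_droplets, 2), dtype=np.int8),
    )
    data = CellVariantData(barcodes=barcodes, variants=variants, DP=dp, AD=ad)
    return data, truth


def mixing_categories(truth: SimTruth) -> np.ndarray:
    """Per-droplet true category "A", "B" or "AB" for a mixing run.

    Same-population doublets are indistinguishable from singlets by genotype
    and are labeled by their population.
    """
    out = []
    for lab in truth.clone_labels:
        if isinstance(lab, tuple):
            out.append("AB" if lab[0] != lab[1] else lab[0])
        else:
            out.append(lab)
    return np.array(out)


def simulate_het_snp_reads(
    n_cells: int,
    n_snps: int,
    ado_q: float,
    mean_depth: float = 50.0,
    depth_dispersion: float = 10.0,
    seed: int = 0,
) -> CellVariantData:
    """Reads at germline SNPs that are truly heterozygous in every cell.

    The substrate for allelic-dropout estimation: with per-allele dropout
    probability ``ado_q``, a fraction ``2 q (1-q)`` of observations lose
    exactly one allele (spuriously homozygous) and ``q**2`` lose both
    (site unobservable, depth forced to 0).
    """
    if n_cells <= 0 or n_snps <= 0:
        raise ConfigError("n_cells and n_snps must be positive")
    if not (0.0 <= ado_q < 1.0):
        raise ConfigError(f"ado_q {ado_q} outside [0,1)")
    rng = np.random.default_rng(seed)
    shape = (n_cells, n_snps)
    dp = _nbinom(rng, np.full(shape, float(mean_depth)), depth_dispersion)
    codes = _het_dropout_codes(rng, shape, ado_q)
    dp[codes == 3] = 0
    ad = rng.binomial(dp, _HET_ALT_FRACTION[codes])
    variants = [
        VariantId(chrom="1", pos=1_000_000 + 500 * j, ref="A", alt="G")
        for j in range(n_snps)
    ]
    barcodes = [f"cell{i:05d}" for i in range(n_cells)]
    return CellVariantData(barcodes=barcodes, variants=variants, DP=dp, AD=ad)
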