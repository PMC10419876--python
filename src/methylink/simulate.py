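"""Synthetic bisulfite + RNA-seq study generator with planted ground truth.

Emulates a two-condition x three-replicate design (iron-sufficient vs
iron-deficient roots) at desk scale: a toy genome with annotated genes,
a fully unmethylated control contig for non-conversion estimation,
per-cytosine read counts from a binomial observation model, and per-gene
expression counts from a negative-binomial model.

Three scenarios set the planted-DMR context mix:

* ``short_term``      - CHH-dominant differential methylation,
* ``long_term``       - CG-dominant differential methylation,
* ``met1_knockdown``  - genome-wide CG methylation loss in the case
  condition (maintenance-methyltransferase knockdown) on top of the
  long-term layout.

A configurable fraction of the genes carrying a planted promoter-CG
hyper region are *coupled*: their expression shift follows the realized
promoter CG delta-ML (log2FC = planted_log2fc x delta/planted_delta), the
pattern of an iron-deficiency-induced transcription factor whose promoter
hypermethylation accompanies induction.  Under ``met1_knockdown`` the
realized promoter delta turns negative, so coupled genes lose their
upregulation.

The observation model for a site with true methylation probability theta:
coverage n ~ Poisson(coverage_mean); methylated count
m ~ Binomial(n, theta (1 - f) + (1 - theta) r) with non-conversion rate
``r`` and under-conversion rate ``f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .contexts import extract_contexts
from .dmr import promoter_interval

CONTROL_CHROM = "control"

SCENARIOS = ("short_term", "long_term", "met1_knockdown")

CONTEXT_MIX = {
    "short_term": {"CHH": 0.7, "CG": 0.2, "CHG": 0.1},
    "long_term": {"CG": 0.7, "CHH": 0.2, "CHG": 0.1},
    "met1_knockdown": {"CG": 0.7, "CHH": 0.2, "CHG": 0.1},
}

CONDITION_LABELS = {
    "short_term": ("Fe_plus", "Fe_minus"),
    "long_term": ("Fe_plus", "Fe_minus"),
    "met1_knockdown": ("wild_type", "met1_rnai"),
}

# gene-body template, 5'->3' (introns derived, not emitted to GFF3)
BODY_SEGMENTS = (
    ("five_prime_UTR", 150),
    ("exon", 300),
    ("intron", 200),
    ("exon", 300),
    ("intron", 200),
    ("exon", 300),
    ("three_prime_UTR", 150),
)
BODY_LENGTH = sum(length for _, length in BODY_SEGMENTS)
TRANSCRIPT_LENGTH = sum(length for kind, length in BODY_SEGMENTS if kind != "intron")
_GENE_MARGIN = 100
_REPEATS_PER_CHROM = 2
_REPEAT_LENGTH = 300
_INTERGENIC_MARGIN = 300


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic dataset."""

    seed: int
    n_chroms: int = 2
    chrom_length: int = 50_000
    n_genes: int = 24
    promoter_length: int = 2_000
    coverage_mean: float = 20.0
    n_replicates: int = 3
    baseline_theta: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.35, "CHG": 0.20, "CHH": 0.05}
    )
    r: float = 0.004
    f: float = 0.0
    scenario: str = "long_term"
    n_planted_dmrs: int = 20
    planted_delta: float = 0.5
    dmr_width: int = 200
    n_planted_degs: int = 12
    planted_log2fc: float = 3.0
    coupled_fraction: float = 0.5
    expression_mean: float = 200.0
    expression_dispersion: float = 0.1
    background_reads: float = 1_000_000.0
    control_length: int = 10_000
    met1_cg_retention: float = 0.25

    def validate(self) -> None:
        for name in ("r", "f", "coupled_fraction", "met1_cg_retention"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for ctx, theta in self.baseline_theta.items():
            if not 0.0 <= theta <= 1.0:
                raise ValueError(f"baseline_theta[{ctx}] must be in [0, 1], got {theta}")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if not 0.0 < self.planted_delta <= 1.0:
            raise ValueError("planted_delta must be in (0, 1]")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        for name in ("n_chroms", "chrom_length", "n_replicates", "dmr_width",
                     "control_length", "promoter_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_genes", "n_planted_dmrs", "n_planted_degs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.expression_dispersion < 0:
            raise ValueError("expression_dispersion must be >= 0")
        if self.background_reads < 0:
            raise ValueError("background_reads must be >= 0")

    @property
    def conditions(self) -> tuple[str, str]:
        """(control, case) condition labels for the scenario."""
        return CONDITION_LABELS[self.scenario]


@dataclass
class Annotation:
    genes: pd.DataFrame        # gene_id, chrom, start, end, strand
    subfeatures: pd.DataFrame  # gene_id, chrom, kind, start, end, strand
    repeats: pd.DataFrame      # chrom, start, end


@dataclass
class SimTruth:
    """Ground-truth ledger for parameter-recovery tests."""

    planted_dmrs: pd.DataFrame  # chrom,start,end,context,direction,true_delta,placement,gene_id
    planted_degs: pd.DataFrame  # gene_id, true_log2fc
    site_theta: pd.DataFrame    # chrom,pos,strand,context,theta_control,theta_case
    coupled_genes: list[str]


@dataclass
class SimDataset:
    config: SimConfig
    genome: dict[str, str]
    annotation: Annotation
    methyl_counts: pd.DataFrame
    design: pd.DataFrame           # sample, condition, replicate
    expr_counts: pd.DataFrame      # genes x samples
    library_sizes: pd.Series       # per-sample mapped-read totals
    gene_lengths: pd.Series
    truth: SimTruth

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {chrom: len(seq) for chrom, seq in self.genome.items()}

    def samples(self, condition: str) -> list[str]:
        return list(self.design.loc[self.design["condition"] == condition, "sample"])

    @property
    def control_samples(self) -> list[str]:
        return self.samples(self.config.conditions[0])

    @property
    def case_samples(self) -> list[str]:
        return self.samples(self.config.conditions[1])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return alphabet[rng.integers(0, 4, int(length))].tobytes().decode("ascii")


def _split_evenly(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], Annotation]:
    """Random genome plus gene models, repeats and the control contig.

    Genes alternate strand for balance; each occupies a fixed-template body
    with a ``promoter_length`` clearance upstream of the TSS.  Raises when
    the requested genes cannot be placed without overlap.  With
    ``n_genes == 0`` only the control contig is emitted.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 11])
    genome: dict[str, str] = {}
    genes, subfeats, repeats = [], [], []
    if config.n_genes > 0:
        per_chrom = _split_evenly(config.n_genes, config.n_chroms)
        footprint = config.promoter_length + BODY_LENGTH + _GENE_MARGIN
        gene_idx = 0
        for ci in range(config.n_chroms):
            chrom = f"chr{ci + 1}"
            genome[chrom] = _random_seq(rng, config.chrom_length)
            n_here = per_chrom[ci]
            blocked: list[tuple[int, int]] = []
            if n_here:
                slot = config.chrom_length // n_here
                if slot < footprint:
                    raise ValueError(
                        f"cannot place {n_here} genes on a {config.chrom_length} bp "
                        f"chromosome without overlap (need {footprint} bp per gene)"
                    )
                for j in range(n_here):
                    slack = slot - footprint
                    offset = int(rng.integers(0, slack + 1))
                    block_start = j * slot + offset
                    strand = "+" if gene_idx % 2 == 0 else "-"
                    if strand == "+":
                        body_start = block_start + config.promoter_length
                    else:
                        body_start = block_start
                    body_end = body_start + BODY_LENGTH
                    gid = f"gene{gene_idx + 1:03d}"
                    genes.append(
                        {"gene_id": gid, "chrom": chrom, "start": body_start,
                         "end": body_end, "strand": strand}
                    )
                    segs = BODY_SEGMENTS if strand == "+" else BODY_SEGMENTS[::-1]
                    pos = body_start
                    for kind, length in segs:
                        if kind != "intron":
                            subfeats.append(
                                {"gene_id": gid, "chrom": chrom, "kind": kind,
                                 "start": pos, "end": pos + length, "strand": strand}
                            )
                        pos += length
                    blocked.append((block_start, block_start + footprint))
                    gene_idx += 1
            for _ in range(_REPEATS_PER_CHROM):
                placed = _place_avoiding(
                    rng, config.chrom_length, _REPEAT_LENGTH, blocked, margin=0, tries=100
                )
                if placed is not None:
                    repeats.append({"chrom": chrom, "start": placed, "end": placed + _REPEAT_LENGTH})
                    blocked.append((placed, placed + _REPEAT_LENGTH))
    genome[CONTROL_CHROM] = _random_seq(rng, config.control_length)
    annotation = Annotation(
        genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"]),
        subfeatures=pd.DataFrame(
            subfeats, columns=["gene_id", "chrom", "kind", "start", "end", "strand"]
        ),
        repeats=pd.DataFrame(repeats, columns=["chrom", "start", "end"]),
    )
    return genome, annotation


def _place_avoiding(
    rng: np.random.Generator,
    chrom_length: int,
    width: int,
    blocked: list[tuple[int, int]],
    margin: int,
    tries: int = 500,
) -> int | None:
    for _ in range(tries):
        start = int(rng.integers(0, chrom_length - width + 1))
        end = start + width
        if all(end + margin <= s or start - margin >= e for s, e in blocked):
            return start
    return None


def _context_counts(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    # largest-remainder rounding, deterministic CG > CHG > CHH tie order
    order = ["CG", "CHG", "CHH"]
    base = {c: int(np.floor(mix[c] * n)) for c in order}
    rem = n - sum(base.values())
    frac = sorted(order, key=lambda c: (-(mix[c] * n - base[c]), order.index(c)))
    for c in frac[:rem]:
        base[c] += 1
    return base


PLANTED_COLUMNS = [
    "chrom", "start", "end", "context", "direction", "true_delta", "placement", "gene_id",
]


def plant_dmrs(config: SimConfig, annotation: Annotation) -> pd.DataFrame:
    """Choose planted DMR regions: context mix per scenario, directions
    alternating hyper/hypo.

    CG regions go to gene promoters (distinct genes, random offset);
    CHG/CHH regions alternate between gene bodies and intergenic space so
    feature-stratified analyses see every stratum.  Regions never overlap
    and keep a clearance from each other.  ``true_delta`` holds the nominal
    +-planted_delta; scenario-level effects (MET1 knockdown) are folded in
    by :func:`simulate_methylome`, which rewrites it to the realized value.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 17])
    if config.n_planted_dmrs == 0 or config.n_genes == 0:
        # a gene-free genome has only the control contig; nothing to plant on
        return pd.DataFrame(columns=PLANTED_COLUMNS)
    for ctx, weight in CONTEXT_MIX[config.scenario].items():
        if weight > 0 and config.baseline_theta[ctx] + config.planted_delta > 1.0:
            raise ValueError(
                f"planted_delta={config.planted_delta} pushes theta outside [0, 1] "
                f"for context {ctx} (baseline {config.baseline_theta[ctx]})"
            )
    counts = _context_counts(config.n_planted_dmrs, CONTEXT_MIX[config.scenario])
    genes = annotation.genes
    gene_pool = list(rng.permutation(genes["gene_id"].to_numpy())) if not genes.empty else []
    chroms = sorted(genes["chrom"].unique()) if not genes.empty else [
        f"chr{i + 1}" for i in range(config.n_chroms)
    ]
    gene_blocks: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    planted_blocks: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    if not genes.empty:
        for g in genes.itertuples(index=False):
            ps, pe = promoter_interval(
                int(g.start), int(g.end), g.strand, config.promoter_length, config.chrom_length
            )
            gene_blocks[g.chrom].append((min(ps, int(g.start)), max(pe, int(g.end))))
    rows = []
    width = config.dmr_width

    def take_gene() -> pd.Series | None:
        if not gene_pool:
            return None
        gid = gene_pool.pop(0)
        return genes.loc[genes["gene_id"] == gid].iloc[0]

    def place_in(interval: tuple[int, int]) -> int:
        lo, hi = interval
        if hi - lo < width:
            raise ValueError(f"planted DMR width {width} does not fit in {interval}")
        return int(rng.integers(lo, hi - width + 1))

    def place_intergenic() -> tuple[str, int] | None:
        # outside gene territory (no margin needed there), but well clear of
        # other planted regions so detected regions cannot merge across truths
        for _ in range(400):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, config.chrom_length - width + 1))
            end = start + width
            if any(end > s0 and start < e0 for s0, e0 in gene_blocks[chrom]):
                continue
            if any(
                end + _INTERGENIC_MARGIN > s0 and start - _INTERGENIC_MARGIN < e0
                for s0, e0 in planted_blocks[chrom]
            ):
                continue
            return chrom, start
        return None

    def add(chrom, start, context, direction, placement, gene_id):
        rows.append(
            {
                "chrom": chrom, "start": start, "end": start + width,
                "context": context, "direction": direction,
                "true_delta": config.planted_delta if direction == "hyper" else -config.planted_delta,
                "placement": placement, "gene_id": gene_id,
            }
        )
        planted_blocks[chrom].append((start, start + width))

    # CG: promoters of distinct genes, alternating hyper/hypo
    for i in range(counts["CG"]):
        direction = "hyper" if i % 2 == 0 else "hypo"
        gene = take_gene()
        if gene is not None:
            interval = promoter_interval(
                int(gene.start), int(gene.end), gene.strand,
                config.promoter_length, config.chrom_length,
            )
            add(gene.chrom, place_in(interval), "CG", direction, "promoter", gene.gene_id)
        else:
            spot = place_intergenic()
            if spot is None:
                raise ValueError("could not place planted CG DMR")
            add(spot[0], spot[1], "CG", direction, "intergenic", pd.NA)
    # CHG/CHH: alternate gene body / gene body / intergenic
    cycle = 0
    for context in ("CHG", "CHH"):
        for i in range(counts[context]):
            direction = "hyper" if i % 2 == 0 else "hypo"
            want_body = cycle % 3 != 2
            cycle += 1
            gene = take_gene() if want_body else None
            if gene is not None:
                add(
                    gene.chrom,
                    place_in((int(gene.start), int(gene.end))),
                    context, direction, "gene_body", gene.gene_id,
                )
            else:
                spot = place_intergenic()
                if spot is None:
                    raise ValueError(f"could not place planted {context} DMR")
                add(spot[0], spot[1], context, direction, "intergenic", pd.NA)
    return pd.DataFrame(rows, columns=PLANTED_COLUMNS)


def simulate_methylome(
    genome: Mapping[str, str],
    annotation: Annotation,
    config: SimConfig,
    planted: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-site bisulfite read counts for every sample, plus truth tables.

    Returns ``(counts, design, site_theta, planted)`` where ``counts`` is a
    tidy table (chrom, pos, strand, context, trinucleotide, sample, m, u),
    ``site_theta`` records the true per-site methylation probability per
    condition and ``planted`` is the input table with ``true_delta``
    rewritten to the realized region mean of theta_case - theta_control.
    """
    config.validate()
    if planted is None:
        planted = plant_dmrs(config, annotation)
    rng = np.random.default_rng([int(config.seed), 23])
    sites = extract_contexts(genome)
    base = sites["context"].map(config.baseline_theta).to_numpy(dtype=float)
    theta_control = base.copy()
    theta_case = base.copy()
    is_control_contig = (sites["chrom"] == CONTROL_CHROM).to_numpy()
    theta_control[is_control_contig] = 0.0
    theta_case[is_control_contig] = 0.0
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    ctx_arr = sites["context"].to_numpy()
    planted = planted.copy()
    masks = []
    for row in planted.itertuples(index=False):
        b = config.baseline_theta[row.context]
        if b + config.planted_delta > 1.0 or b < 0.0:
            raise ValueError(
                f"planted_delta={config.planted_delta} pushes theta outside [0, 1] "
                f"for context {row.context}"
            )
        mask = (
            (chrom_arr == row.chrom)
            & (pos_arr >= row.start)
            & (pos_arr < row.end)
            & (ctx_arr == row.context)
        )
        masks.append(mask)
        if row.direction == "hyper":
            theta_case[mask] = b + config.planted_delta
        else:
            theta_control[mask] = b + config.planted_delta
    if config.scenario == "met1_knockdown":
        theta_case[ctx_arr == "CG"] *= config.met1_cg_retention
    realized = []
    for row, mask in zip(planted.itertuples(index=False), masks):
        if mask.any():
            realized.append(float(np.mean(theta_case[mask] - theta_control[mask])))
        else:  # no site of that context in the region (vanishingly rare)
            b = config.baseline_theta[row.context]
            hi = b + config.planted_delta
            if config.scenario == "met1_knockdown" and row.context == "CG":
                delta = (hi if row.direction == "hyper" else b) * config.met1_cg_retention - (
                    b if row.direction == "hyper" else hi
                )
            else:
                delta = hi - b if row.direction == "hyper" else b - hi
            realized.append(delta)
    planted["true_delta"] = realized
    site_theta = sites[["chrom", "pos", "strand", "context"]].copy()
    site_theta["theta_control"] = theta_control
    site_theta["theta_case"] = theta_case
    control_label, case_label = config.conditions
    frames = []
    design_rows = []
    n_sites = len(sites)
    site_cols = sites[["chrom", "pos", "strand", "context", "trinucleotide"]]
    for condition, theta in ((control_label, theta_control), (case_label, theta_case)):
        p_read = theta * (1.0 - config.f) + (1.0 - theta) * config.r
        for rep in range(1, config.n_replicates + 1):
            sample = f"{condition}_{rep}"
            design_rows.append({"sample": sample, "condition": condition, "replicate": rep})
            n = rng.poisson(config.coverage_mean, n_sites)
            m = rng.binomial(n, p_read)
            frame = site_cols.copy()
            frame["sample"] = sample
            frame["m"] = m
            frame["u"] = n - m
            frames.append(frame)
    counts = pd.concat(frames, ignore_index=True)
    design = pd.DataFrame(design_rows)
    return counts, design, site_theta, planted


def simulate_expression(
    annotation: Annotation,
    config: SimConfig,
    planted: pd.DataFrame,
    site_theta: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series, pd.DataFrame, list[str]]:
    """Per-gene read counts with planted DEGs and methylation coupling.

    Returns ``(counts, design, library_sizes, gene_lengths, planted_degs,
    coupled_genes)``.  Counts follow a negative binomial (gamma-Poisson)
    with fixed dispersion; the case-condition mean of a planted DEG is
    shifted by 2**log2FC.  Coupled genes (a ``coupled_fraction`` of the
    genes with planted promoter-CG hyper regions) get log2FC =
    planted_log2fc x realized_promoter_delta / planted_delta, tying
    transcription to the realized promoter methylation change.

    The annotated gene panel is a small window of a transcriptome, so each
    sample's mapped-read total (the RPKM denominator) is the panel's count
    sum plus a Poisson background of ``background_reads`` representing the
    unmodelled remainder of the library; this keeps library sizes stable
    against planted fold changes, as in a genome-scale experiment.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 31])
    genes = list(annotation.genes["gene_id"])
    control_label, case_label = config.conditions
    design_rows = [
        {"sample": f"{cond}_{rep}", "condition": cond, "replicate": rep}
        for cond in (control_label, case_label)
        for rep in range(1, config.n_replicates + 1)
    ]
    design = pd.DataFrame(design_rows)
    gene_lengths = pd.Series(TRANSCRIPT_LENGTH, index=pd.Index(genes, name="gene_id"), dtype=int)
    if not genes:
        empty = pd.DataFrame(index=gene_lengths.index, columns=design["sample"], dtype=int)
        lib = pd.Series(
            rng.poisson(config.background_reads, len(design)),
            index=design["sample"], dtype=float,
        )
        return (empty, design, lib, gene_lengths,
                pd.DataFrame(columns=["gene_id", "true_log2fc"]), [])
    base_mean = rng.lognormal(np.log(config.expression_mean), 1.0, len(genes))
    prom_hyper = planted[
        (planted["placement"] == "promoter")
        & (planted["context"] == "CG")
        & (planted["direction"] == "hyper")
    ]
    n_coupled = min(
        int(round(config.coupled_fraction * len(prom_hyper))), config.n_planted_degs
    )
    coupled_genes = list(prom_hyper["gene_id"].iloc[:n_coupled])
    lfc = dict.fromkeys(genes, 0.0)
    for gid in coupled_genes:
        realized = float(
            planted.loc[
                (planted["gene_id"] == gid) & (planted["placement"] == "promoter"),
                "true_delta",
            ].iloc[0]
        )
        lfc[gid] = config.planted_log2fc * realized / config.planted_delta
    planted_deg_genes = list(coupled_genes)
    sign = 1.0
    body_genes = [
        g for g in planted.loc[planted["placement"] == "gene_body", "gene_id"].dropna().unique()
        if g not in planted_deg_genes
    ]
    for gid in body_genes:
        if len(planted_deg_genes) >= config.n_planted_degs:
            break
        lfc[gid] = sign * config.planted_log2fc
        sign = -sign
        planted_deg_genes.append(gid)
    remaining = [g for g in rng.permutation(genes) if g not in planted_deg_genes]
    for gid in remaining:
        if len(planted_deg_genes) >= config.n_planted_degs:
            break
        lfc[gid] = sign * config.planted_log2fc
        sign = -sign
        planted_deg_genes.append(gid)
    planted_degs = pd.DataFrame(
        {"gene_id": planted_deg_genes, "true_log2fc": [lfc[g] for g in planted_deg_genes]}
    )
    lfc_arr = np.array([lfc[g] for g in genes])
    counts = {}
    disp = config.expression_dispersion
    for row in design.itertuples(index=False):
        mu = base_mean * (2.0 ** lfc_arr if row.condition == case_label else 1.0)
        if disp > 0:
            lam = rng.gamma(1.0 / disp, mu * disp)
        else:
            lam = mu
        counts[row.sample] = rng.poisson(lam)
    expr = pd.DataFrame(counts, index=gene_lengths.index)
    library_sizes = expr.sum(axis=0).astype(float) + rng.poisson(
        config.background_reads, expr.shape[1]
    )
    library_sizes.index.name = "sample"
    return expr, design, library_sizes, gene_lengths, planted_degs, coupled_genes


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Run the full generator: genome, planted truth, methylome, expression."""
    genome, annotation = simulate_genome(config)
    planted = plant_dmrs(config, annotation)
    methyl_counts, design, site_theta, planted = simulate_methylome(
        genome, annotation, config, planted
    )
    expr, _expr_design, library_sizes, gene_lengths, planted_degs, coupled = (
        simulate_expression(annotation, config, planted)
    )
    truth = SimTruth(
        planted_dmrs=planted,
        planted_degs=planted_degs,
        site_theta=site_theta,
        coupled_genes=coupled,
    )
    return SimDataset(
        config=replace(config),
        genome=genome,
        annotation=annotation,
        methyl_counts=methyl_counts,
        design=design,
        expr_counts=expr,
        library_sizes=library_sizes,
        gene_lengths=gene_lengths,
        truth=truth,
    )
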