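"""Synthetic-data generators emulating the study design.

The generators produce every input the pipeline consumes, with the
statistical structure the downstream analysis assumes, plus a
:class:`TruthSet` so recovery can be scored:

* per-CpG bisulfite count tables for 4 diet groups (Ctrl, 7FD, 10FS, 20FS)
  x 2 tissues (placenta, cortex), n replicates per group, negative-binomial
  coverage and beta-binomial methylation counts around per-tile baselines,
  with differentially methylated tiles planted at chosen effect sizes;
* 100-bp reference methylation tracks for sperm, germinal-vesicle oocyte
  (GVO) and the maternal allele of the inner cell mass (ICMm), with a
  designated subset of maternally-inherited regions split among
  gain/stable/loss dynamics;
* dam-level litter records (corpora lutea, implantation sites, resorptions)
  and embryo-level weights with diet-dependent parameters.

Every generator is a pure function of its :class:`SimConfig`; the seed
fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .rrbs_io import DIETS, TISSUES, SampleMethylome

__all__ = [
    "SimConfig", "LitterParams", "PlantedDmt", "TruthSet",
    "gen_methylomes", "gen_reference_tracks", "gen_litters", "gen_gene_model",
    "eligible_tiles",
]


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class PlantedDmt:
    """A tile-level methylation effect planted into treated groups.

    ``tile_index`` addresses the genome-wide 100-bp tile grid (tiles
    numbered consecutively chromosome by chromosome).  ``delta`` is in
    percentage points and is added to the tile's baseline methylation in
    the affected diets/tissues.
    """

    tile_index: int
    delta: float
    diets: tuple = ("7FD", "10FS", "20FS")
    tissues: tuple = ("placenta", "cortex")


@dataclass(frozen=True)
class LitterParams:
    """Per-diet reproductive-outcome distribution parameters.

    Counts follow the natural hierarchy: corpora lutea (CL) ~ Poisson,
    implantations = CL minus binomial pre-implantation loss, resorptions
    ~ Binomial(implants, p_resorption); embryo weight is normal per diet.
    """

    n_litters: int = 12
    cl_mean: float = 11.0
    p_preimplantation_loss: float = 0.10
    p_resorption: float = 0.05
    weight_mean: float = 1.25       # grams at E18.5
    weight_sd: float = 0.12
    placenta_weight_mean: float = 0.085
    placenta_weight_sd: float = 0.010
    crown_rump_mean: float = 22.0   # mm
    crown_rump_sd: float = 1.2
    p_malformed: float = 0.02

    def validate(self):
        for name in ("p_preimplantation_loss", "p_resorption", "p_malformed"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimConfigError(f"{name}={v} outside [0, 1]")
        if self.cl_mean < 0 or self.weight_sd < 0:
            raise SimConfigError("negative distribution parameter")


#: resorption risk elevated in the 20-fold supplemented group, matching the
#: direction of the reproductive phenotype the design probes.
DEFAULT_LITTER_PARAMS = {
    "Ctrl": LitterParams(p_resorption=0.05),
    "7FD": LitterParams(p_resorption=0.09),
    "10FS": LitterParams(p_resorption=0.08),
    "20FS": LitterParams(p_resorption=0.18),
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic study.

    Defaults describe a desk-scale toy genome (2 chromosomes of 1 Mb,
    ~10 CpGs/kb -> ~20,000 tiles) with the study's group structure:
    4 diets x 2 tissues x ``n_replicates`` samples, negative-binomial
    CpG coverage and beta-binomial methylation counts.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 1_000_000
    cpg_density: float = 10.0            # expected CpGs per kb, genome-wide
    cpg_cluster_size: float = 8.0        # mean CpGs per cluster (MspI-fragment-like)
    cpg_cluster_spacing: float = 10.0    # mean bp between CpGs within a cluster
    tile_size: int = 100
    n_replicates: int = 6
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0     # negative-binomial size parameter
    baseline_beta_a: float = 0.4
    baseline_beta_b: float = 0.4
    overdispersion_rho: float = 0.005    # within-CpG beta-binomial correlation
    dropout: float = 0.02                # per-sample fraction of CpGs unobserved
    diets: tuple = DIETS
    tissues: tuple = TISSUES
    planted_dmts: tuple = ()
    n_maternal_regions: int = 300
    track_dropout: float = 0.02          # regions missing from a reference track
    litter_params: dict = field(default_factory=lambda: dict(DEFAULT_LITTER_PARAMS))

    # -- grid helpers ------------------------------------------------------
    @property
    def tiles_per_chrom(self) -> int:
        return self.chrom_len // self.tile_size

    @property
    def n_tiles(self) -> int:
        return self.n_chroms * self.tiles_per_chrom

    def chrom_names(self):
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def tile_coords(self, tile_index: int):
        """(chrom, start) of a genome-wide tile index (0-based half-open)."""
        c, k = divmod(int(tile_index), self.tiles_per_chrom)
        return self.chrom_names()[c], k * self.tile_size

    def validate(self):
        if self.n_chroms < 1 or self.chrom_len < self.tile_size:
            raise SimConfigError("genome too small")
        if not (0.0 <= self.overdispersion_rho < 1.0):
            raise SimConfigError("overdispersion_rho must be in [0, 1)")
        if not (0.0 <= self.dropout < 1.0):
            raise SimConfigError("dropout must be in [0, 1)")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise SimConfigError("coverage parameters must be positive")
        for p in self.planted_dmts:
            if not (0 <= p.tile_index < self.n_tiles):
                raise SimConfigError(f"planted tile_index {p.tile_index} outside grid")
            lo, hi = _feasible_baseline(p.delta)
            if lo >= hi:
                raise SimConfigError(
                    f"planted delta {p.delta} pp cannot keep methylation within [0, 100]")
            for d in p.diets:
                if d not in self.diets:
                    raise SimConfigError(f"planted diet {d!r} not simulated")
        for diet, lp in self.litter_params.items():
            lp.validate()

    def with_random_plants(self, n_planted: int = 60,
                           delta_range: tuple = (10.0, 25.0),
                           hyper_fraction: float = 0.8,
                           shared_fraction: float = 0.1,
                           plant_min_cpgs: int = 4,
                           diets: Sequence[str] = ("7FD", "10FS", "20FS")) -> "SimConfig":
        """Plant ``n_planted`` DMTs per treated diet at random CpG-dense tiles.

        Plants target tiles with >= ``plant_min_cpgs`` CpGs — the CpG-dense
        substrate the tiling analysis tests, where a tile-level effect is a
        well-defined quantity.  Effect sizes are uniform over
        ``delta_range`` with ``hyper_fraction`` positive; a
        ``shared_fraction`` of each diet's plants affects both tissues with
        the same sign (the rest are placenta-only), so the cross-tissue
        intersection logic sees realistic partial overlap.
        """
        rng = np.random.default_rng([int(self.seed), 901])
        pool = eligible_tiles(self, min_cpgs=plant_min_cpgs)
        if len(pool) < n_planted:
            raise SimConfigError("not enough CpG-bearing tiles to plant into")
        plants = []
        for diet in diets:
            tiles = rng.choice(pool, size=n_planted, replace=False)
            deltas = rng.uniform(*delta_range, size=n_planted)
            signs = np.where(rng.random(n_planted) < hyper_fraction, 1.0, -1.0)
            shared = rng.random(n_planted) < shared_fraction
            for t, d, s, sh in zip(tiles, deltas, signs, shared):
                tis = tuple(self.tissues) if sh else (self.tissues[0],)
                plants.append(PlantedDmt(int(t), float(s * d), (diet,), tis))
        return replace(self, planted_dmts=tuple(plants))


@dataclass
class TruthSet:
    """Ground truth of one simulation, addressable by coordinate."""

    planted_dmts: pd.DataFrame = field(default_factory=pd.DataFrame)
    maternal_regions: pd.DataFrame = field(default_factory=pd.DataFrame)
    litter_params: dict = field(default_factory=dict)


def _feasible_baseline(delta: float, margin: float = 2.0):
    """Baseline range (percent) keeping baseline + delta inside [0, 100]."""
    lo = max(margin, -delta + margin)
    hi = min(100.0 - margin, 100.0 - delta - margin)
    return lo, hi


def _cpg_positions(cfg: SimConfig) -> pd.DataFrame:
    """Clustered CpG positions (1-based), shared by all samples.

    CpGs come in clusters (geometric size, short within-cluster spacing)
    whose density is set so the genome-wide rate matches ``cpg_density``,
    mimicking the CpG-dense MspI fragments an RRBS library enriches for.
    Drawn from a dedicated substream of the seed so planting helpers and
    the methylome generator see identical positions.
    """
    rng = np.random.default_rng([int(cfg.seed), 100])
    frames = []
    cluster_rate = cfg.cpg_density / 1000.0 / cfg.cpg_cluster_size  # clusters per bp
    for chrom in cfg.chrom_names():
        n_clusters = rng.poisson(cfg.chrom_len * cluster_rate)
        centers = rng.integers(1, cfg.chrom_len + 1, size=n_clusters)
        sizes = rng.geometric(1.0 / cfg.cpg_cluster_size, size=n_clusters)
        gaps = 2 + rng.geometric(1.0 / cfg.cpg_cluster_spacing, size=int(sizes.sum()))
        offsets = np.concatenate([np.cumsum(gaps[a:b]) - gaps[a]
                                  for a, b in zip(np.r_[0, np.cumsum(sizes)[:-1]],
                                                  np.cumsum(sizes))]) if n_clusters else np.array([], int)
        pos = np.repeat(centers, sizes) + offsets
        pos = np.unique(pos[(pos >= 1) & (pos <= cfg.chrom_len)])
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    return pd.concat(frames, ignore_index=True)


def _tile_index_of(cfg: SimConfig, cpgs: pd.DataFrame) -> np.ndarray:
    chrom_index = {c: i for i, c in enumerate(cfg.chrom_names())}
    return (cpgs["chrom"].map(chrom_index).to_numpy() * cfg.tiles_per_chrom
            + (cpgs["pos"].to_numpy() - 1) // cfg.tile_size)


def eligible_tiles(cfg: SimConfig, min_cpgs: int = 2) -> np.ndarray:
    """Tile indices containing >= ``min_cpgs`` CpGs (plantable targets)."""
    tile_idx = _tile_index_of(cfg, _cpg_positions(cfg))
    idx, counts = np.unique(tile_idx, return_counts=True)
    return idx[counts >= min_cpgs]


def gen_methylomes(cfg: SimConfig):
    """Simulate per-CpG count tables for every sample.

    Returns ``(samples, truth)`` where ``samples`` is a list of
    :class:`SampleMethylome` (matched replicate ids across tissues) and
    ``truth`` records the planted DMT coordinates and true deltas.

    Per CpG and sample: coverage ~ NB(mean, dispersion) floored at 1;
    methylated count ~ beta-binomial with mean equal to the tile baseline
    (plus the planted delta in affected diet/tissue groups) and
    correlation ``overdispersion_rho``.
    """
    cfg.validate()
    rng = np.random.default_rng([int(cfg.seed), 101])
    cpgs = _cpg_positions(cfg)
    tile_of_cpg = _tile_index_of(cfg, cpgs)

    baseline = rng.beta(cfg.baseline_beta_a, cfg.baseline_beta_b, size=cfg.n_tiles)
    plant_delta = {}  # (tile, diet, tissue) -> delta fraction
    for p in cfg.planted_dmts:
        lo, hi = _feasible_baseline(p.delta)
        baseline[p.tile_index] = rng.uniform(lo, hi) / 100.0
        for d in p.diets:
            for t in p.tissues:
                plant_delta[(p.tile_index, d, t)] = (
                    plant_delta.get((p.tile_index, d, t), 0.0) + p.delta / 100.0)

    n_cpg = len(cpgs)
    size = cfg.coverage_dispersion
    p_nb = size / (size + cfg.coverage_mean)
    rho = cfg.overdispersion_rho

    samples = []
    for tissue in cfg.tissues:
        for diet in cfg.diets:
            for rep in range(1, cfg.n_replicates + 1):
                p_cpg = baseline[tile_of_cpg].copy()
                for (tile, d, t), dl in plant_delta.items():
                    if d == diet and t == tissue:
                        p_cpg[tile_of_cpg == tile] += dl
                p_cpg = np.clip(p_cpg, 1e-6, 1 - 1e-6)
                cov = np.maximum(rng.negative_binomial(size, p_nb, size=n_cpg), 1)
                if rho > 0:
                    a = p_cpg * (1 - rho) / rho
                    b = (1 - p_cpg) * (1 - rho) / rho
                    p_draw = rng.beta(a, b)
                else:
                    p_draw = p_cpg
                meth = rng.binomial(cov, p_draw)
                keep = rng.random(n_cpg) >= cfg.dropout
                rec = pd.DataFrame({
                    "chrom": cpgs["chrom"][keep].to_numpy(),
                    "pos": cpgs["pos"][keep].to_numpy(),
                    "count_meth": meth[keep],
                    "count_unmeth": (cov - meth)[keep],
                })
                samples.append(SampleMethylome(
                    sample_id=f"{tissue}_{diet}_r{rep}", tissue=tissue,
                    diet=diet, sex="M", records=rec))

    truth_rows = []
    for p in cfg.planted_dmts:
        chrom, start = cfg.tile_coords(p.tile_index)
        for d in p.diets:
            for t in p.tissues:
                truth_rows.append((chrom, start, start + cfg.tile_size,
                                   p.delta, d, t, 100.0 * baseline[p.tile_index]))
    truth = TruthSet(planted_dmts=pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "delta", "diet", "tissue",
                             "baseline_percent"]))
    return samples, truth


# ---------------------------------------------------------------------------
# Reference tracks

def gen_reference_tracks(cfg: SimConfig):
    """Simulate sperm / GVO / ICMm 100-bp methylation tracks plus truth.

    A designated subset of ``n_maternal_regions`` tiles satisfies the
    maternal-inheritance gates by construction (sperm <= 10, GVO and ICMm
    >= 25) and is split evenly among gain / stable / loss dynamics using
    the +-10 pp GVO->ICM rule with a safety margin; every non-designated
    region violates at least one gate.  A small fraction of regions is
    dropped independently from each track to exercise coordinate matching.

    Returns ``(tracks, truth)``: ``tracks`` maps source name to a
    DataFrame (chrom, start, end, meth_percent); ``truth.maternal_regions``
    lists the designated regions present in all three tracks with their
    dynamic class.
    """
    cfg.validate()
    rng = np.random.default_rng([int(cfg.seed), 202])
    n = cfg.n_tiles
    if cfg.n_maternal_regions > n:
        raise SimConfigError("n_maternal_regions exceeds tile grid")

    sperm = np.empty(n)
    gvo = np.empty(n)
    icm = np.empty(n)
    maternal_idx = rng.choice(n, size=cfg.n_maternal_regions, replace=False)
    is_maternal = np.zeros(n, dtype=bool)
    is_maternal[maternal_idx] = True

    # non-designated regions fail one of the three gates, chosen at random
    other = ~is_maternal
    n_other = other.sum()
    mode = rng.integers(0, 3, size=n_other)
    s = np.where(mode == 0, rng.uniform(15, 90, n_other), rng.uniform(0, 10, n_other))
    g = np.where(mode == 1, rng.uniform(0, 20, n_other), rng.uniform(25, 95, n_other))
    i = np.where(mode == 2, rng.uniform(0, 20, n_other), rng.uniform(25, 95, n_other))
    sperm[other], gvo[other], icm[other] = s, g, i

    classes = np.array(["gain", "stable", "loss"])[
        np.arange(cfg.n_maternal_regions) % 3]
    rng.shuffle(classes)
    sm = rng.uniform(0, 10, cfg.n_maternal_regions)
    gv = np.empty(cfg.n_maternal_regions)
    ic = np.empty(cfg.n_maternal_regions)
    for k, cls in enumerate(classes):
        if cls == "gain":
            gv[k] = rng.uniform(25, 60)
            ic[k] = gv[k] + rng.uniform(10.5, 35)
        elif cls == "loss":
            gv[k] = rng.uniform(40, 95)
            ic[k] = rng.uniform(25, gv[k] - 10.5)
        else:  # stable: |GVO - ICM| < 10 by construction
            gv[k] = rng.uniform(30, 90)
            ic[k] = np.clip(gv[k] + rng.uniform(-8, 8), 25, 100)
    sperm[maternal_idx], gvo[maternal_idx], icm[maternal_idx] = sm, gv, ic

    chroms = np.repeat(cfg.chrom_names(), cfg.tiles_per_chrom)
    starts = np.tile(np.arange(cfg.tiles_per_chrom) * cfg.tile_size, cfg.n_chroms)
    grid = pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + cfg.tile_size})

    tracks = {}
    present = np.ones(n, dtype=bool)
    for name, vals in (("sperm", sperm), ("GVO", gvo), ("ICMm", icm)):
        keep = rng.random(n) >= cfg.track_dropout
        present &= keep
        tr = grid[keep].copy()
        tr["meth_percent"] = np.round(vals[keep], 3)
        tracks[name] = tr.reset_index(drop=True)

    truth_mask = is_maternal & present
    order = np.argsort(maternal_idx)
    midx_sorted = maternal_idx[order]
    truth = grid.iloc[midx_sorted].copy()
    truth["sperm_meth"] = np.round(sperm[midx_sorted], 3)
    truth["gvo_meth"] = np.round(gvo[midx_sorted], 3)
    truth["icm_meth"] = np.round(icm[midx_sorted], 3)
    truth["dynamic_class"] = classes[order]
    truth["gvo_high"] = truth["gvo_meth"] >= 75.0
    truth = truth[present[midx_sorted]].reset_index(drop=True)
    return tracks, TruthSet(maternal_regions=truth)


# ---------------------------------------------------------------------------
# Gene models

def gen_gene_model(cfg: SimConfig, n_genes_per_mb: int = 55,
                   n_exons_mean: float = 5.0, exon_len_mean: int = 200,
                   intron_len_mean: int = 1500):
    """Simulate a BED-like gene model on the toy genome.

    Genes are placed uniformly with alternating exon/intron structure
    (geometric exon count, exponential-ish lengths); defaults give a
    genic + promoter footprint of roughly three quarters of the genome,
    so about a quarter of tiles are intergenic — the background mixture
    the enrichment analysis expects of a gene-rich RRBS fraction.

    Returns a DataFrame (chrom, start, end, feature, gene_id, strand)
    with promoter/exon/intron rows, ready for
    :class:`foltile.rrbs_io.GeneModel` or to be written as BED.
    """
    cfg.validate()
    rng = np.random.default_rng([int(cfg.seed), 404])
    rows = []
    gid = 0
    for chrom in cfg.chrom_names():
        n_genes = rng.poisson(n_genes_per_mb * cfg.chrom_len / 1e6)
        starts = np.sort(rng.integers(0, cfg.chrom_len, size=n_genes))
        for s in starts:
            gid += 1
            gene_id = f"gene{gid:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = 1 + rng.geometric(1.0 / n_exons_mean)
            pos = int(s)
            parts = []
            for e in range(n_ex):
                ex_len = max(30, int(rng.exponential(exon_len_mean)))
                parts.append((pos, pos + ex_len, "exon"))
                pos += ex_len
                if e < n_ex - 1:
                    in_len = max(60, int(rng.exponential(intron_len_mean)))
                    parts.append((pos, pos + in_len, "intron"))
                    pos += in_len
            if pos > cfg.chrom_len:
                continue
            tss = s if strand == "+" else pos
            if strand == "+":
                p_start, p_end = max(0, s - 2000), s + 500
            else:
                p_start, p_end = max(0, pos - 500), pos + 2000
            rows.append((chrom, p_start, p_end, "promoter", gene_id, strand))
            rows.extend((chrom, a, b, f, gene_id, strand) for a, b, f in parts)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "feature", "gene_id", "strand"])


# ---------------------------------------------------------------------------
# Litters

def gen_litters(cfg: SimConfig):
    """Simulate dam-level litter records and embryo-level measurements.

    Returns ``(litters, embryos)`` DataFrames matching the tabular input
    formats in :mod:`foltile.rrbs_io`.  Per dam: CL ~ Poisson(cl_mean),
    implants = CL - Binomial(CL, p_preimplantation_loss), resorptions ~
    Binomial(implants, p_resorption); each viable embryo gets weight,
    placenta weight, sex, crown-rump length and a malformation flag.
    """
    cfg.validate()
    rng = np.random.default_rng([int(cfg.seed), 303])
    litter_rows, embryo_rows = [], []
    for diet in cfg.diets:
        lp = cfg.litter_params.get(diet)
        if lp is None:
            raise SimConfigError(f"no litter parameters for diet {diet!r}")
        for j in range(1, lp.n_litters + 1):
            dam = f"{diet}_dam{j}"
            cl = int(rng.poisson(lp.cl_mean))
            implants = cl - int(rng.binomial(cl, lp.p_preimplantation_loss)) if cl else 0
            resorptions = int(rng.binomial(implants, lp.p_resorption)) if implants else 0
            viable = implants - resorptions
            litter_rows.append((dam, diet, cl, implants, resorptions))
            for e in range(1, viable + 1):
                w = max(0.05, rng.normal(lp.weight_mean, lp.weight_sd))
                pw = max(0.01, rng.normal(lp.placenta_weight_mean, lp.placenta_weight_sd))
                embryo_rows.append((
                    dam, f"{dam}_e{e}", round(w, 4), round(pw, 4),
                    "M" if rng.random() < 0.5 else "F",
                    round(max(5.0, rng.normal(lp.crown_rump_mean, lp.crown_rump_sd)), 2),
                    bool(rng.random() < lp.p_malformed)))
    litters = pd.DataFrame(litter_rows, columns=[
        "dam_id", "diet", "corpora_lutea", "implantation_sites", "resorptions"])
    embryos = pd.DataFrame(embryo_rows, columns=[
        "dam_id", "embryo_id", "weight", "placenta_weight", "sex", "crown_rump", "malformed"])
    return litters, embryos
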