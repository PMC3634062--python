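"""Paired two-platform synthetic expression data with known ground truth.

The generator emulates a developmental expression atlas measured twice on the
same RNA samples: 18 tissues x 3 biological replicates profiled by RNA-Seq
(negative-binomial counts converted to FPKM) and by a two-color style
oligonucleotide microarray (background floor, saturation ceiling,
cross-hybridization between paralogs).  Both platforms observe the same latent
log-expression surface, built from per-gene baselines plus co-expression
module loadings on shared tissue factors; tissues within a declared group
(e.g. the leaf-like or endosperm-like samples) share factor values and hence
co-cluster.

Three platform-specific artifact classes are injected and recorded as ground
truth for recovery experiments:

* ``saturated_genes`` -- whole profiles shifted so latent expression sits
  above the microarray ceiling in most tissues: the array signal is clipped
  (flat at the maximum measurable value) while RNA-Seq tracks the full
  dynamic range;
* ``low_count_genes`` -- negative-binomial means scaled down so that most
  tissues yield zero counts, the regime that produces spurious correlations
  among barely-detected genes (the count-noise mechanism is preserved rather
  than zeroing values post hoc);
* paralog pairs with mismatch-dependent probe cross-hybridization ("bleed"):
  probes 2-3 mismatches away from a paralog pick up a sizable fraction of the
  partner's signal, while 5+ mismatches hybridize specifically.  Pair members
  are tissue-specific (each prefers one tissue group, like an
  endosperm-specific gene paired with its leaf-specific duplicate), so bleed
  paints the partner's contrasting profile onto the array signal.

``divergent_genes`` is the union of the three artifact sets and is the
recovery target for the expression-conservation pipeline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, write_expression_table

MISMATCH_CLASSES = ("2-3", "5+")

# two coherent tissue groups (leaf-like, seed-like); the remaining twelve
# tissues are developmentally distinct singletons
_DEFAULT_GROUPS = ((0, 1, 2), (3, 4, 5))


class SizingError(ValueError):
    """Requested module/artifact sizes exceed the gene universe."""


@dataclass
class SyntheticConfig:
    """Parameters of the paired-platform simulation.

    Defaults mirror the study design being emulated: 18 tissues (two
    biologically coherent groups plus twelve developmentally distinct
    singletons), 3 replicates, a 16-bit scanner ceiling with a background
    floor, and bleed 0.3 for probes 2-3 mismatches from a paralog versus
    none at 5+ mismatches.
    """

    n_genes: int = 2000
    n_tissues: int = 18
    n_replicates: int = 3
    n_modules: int = 100
    tissue_groups: tuple = _DEFAULT_GROUPS
    module_size_range: tuple = (20, 20)
    paralog_fraction: float = 0.04
    paralog_bleed: dict = field(default_factory=lambda: {"2-3": 0.3, "5+": 0.0})
    paralog_contrast: float = 2.0         # natural-log boost in the preferred group
    paralog_partner_boost: float = 1.4    # extra baseline for the abundant member
    paralog_baseline: tuple = (1.4, 0.4)  # baseline mean/SD for pair members, so
                                          # their peaks stay inside the array range
    frac_saturated: float = 0.02
    saturation_ceiling: float = 65535.0   # 2^16 - 1 scanner maximum
    background_floor: float = 32.0
    intensity_scale: float = 400.0
    nb_dispersion: float = 0.05
    depth_per_tissue: tuple | None = None  # reads per replicate; default 5e6
    noise_sd: float = 0.15                # log-scale replicate noise SD
    frac_low_expressed: float = 0.07
    low_count_mean: float = 0.1           # target mean count/replicate for low genes
    n_saturated_tissues: int = 18         # tissues clipped at the array ceiling
    baseline_log_mean: float = 3.0        # natural-log FPKM-scale baseline
    baseline_log_sd: float = 1.0
    factor_sd: float = 1.0
    module_mixing: float = 0.6            # max secondary-module loading share
    loading_range: tuple = (0.8, 1.2)
    transcript_length_range_kb: tuple = (0.5, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_genes", "n_tissues", "n_replicates", "n_modules"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("paralog_fraction", "frac_saturated", "frac_low_expressed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for cls, b in self.paralog_bleed.items():
            if not 0.0 <= b < 1.0:
                raise ValueError(f"paralog_bleed[{cls!r}] must be in [0, 1)")
        if not self.saturation_ceiling > self.background_floor > 0:
            raise ValueError("need saturation_ceiling > background_floor > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        lo, hi = self.module_size_range
        if lo < 1 or hi < lo:
            raise ValueError("module_size_range must satisfy 1 <= lo <= hi")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        flat = [t for g in self.tissue_groups for t in g]
        if len(flat) != len(set(flat)) or any(
                not 0 <= t < self.n_tissues for t in flat):
            raise ValueError("tissue_groups must be disjoint valid tissue indices")
        if self.depth_per_tissue is not None and \
                len(self.depth_per_tissue) != self.n_tissues:
            raise ValueError("depth_per_tissue length must equal n_tissues")

    @property
    def depths(self) -> np.ndarray:
        if self.depth_per_tissue is None:
            return np.full(self.n_tissues, 5e6)
        return np.asarray(self.depth_per_tissue, dtype=float)

    @classmethod
    def exchangeable(cls, **kwargs) -> "SyntheticConfig":
        """A configuration with every platform-specific artifact switched off.

        No saturation, no low-count depletion, no probe bleed and a
        background floor that is negligible against the signal, so the two
        platforms are interchangeable observations of the same latent
        transcriptome (up to their respective measurement noise).
        """
        defaults = dict(
            frac_saturated=0.0,
            frac_low_expressed=0.0,
            paralog_bleed={"2-3": 0.0, "5+": 0.0},
            background_floor=1.0,
            saturation_ceiling=1e12,
        )
        defaults.update(kwargs)
        return cls(**defaults)


@dataclass
class SyntheticTruth:
    """Ground truth backing a simulated dataset."""

    latent_log_expression: pd.DataFrame   # gene x tissue, natural-log scale
    module_of_gene: pd.Series             # gene -> module id (-1 = none)
    paralog_pairs: list                   # (gene_a, gene_b, mismatch_class)
    saturated_genes: set
    low_count_genes: set
    divergent_genes: set
    transcript_length_kb: pd.Series
    tissue_group_of: pd.Series            # tissue -> group id (-1 = ungrouped)

    @property
    def gene_ids(self) -> pd.Index:
        return self.latent_log_expression.index

    @property
    def tissue_ids(self) -> list:
        return list(self.latent_log_expression.columns)

    def to_json(self, path) -> None:
        payload = {
            "latent_log_expression": {
                "index": list(self.latent_log_expression.index),
                "columns": list(self.latent_log_expression.columns),
                "values": self.latent_log_expression.to_numpy().tolist(),
            },
            "module_of_gene": self.module_of_gene.astype(int).to_dict(),
            "paralog_pairs": [list(p) for p in self.paralog_pairs],
            "saturated_genes": sorted(self.saturated_genes),
            "low_count_genes": sorted(self.low_count_genes),
            "divergent_genes": sorted(self.divergent_genes),
            "transcript_length_kb": self.transcript_length_kb.to_dict(),
            "tissue_group_of": self.tissue_group_of.astype(int).to_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        lat = d["latent_log_expression"]
        frame = pd.DataFrame(lat["values"], index=lat["index"], columns=lat["columns"])
        return cls(
            latent_log_expression=frame,
            module_of_gene=pd.Series(d["module_of_gene"]),
            paralog_pairs=[tuple(p) for p in d["paralog_pairs"]],
            saturated_genes=set(d["saturated_genes"]),
            low_count_genes=set(d["low_count_genes"]),
            divergent_genes=set(d["divergent_genes"]),
            transcript_length_kb=pd.Series(d["transcript_length_kb"]),
            tissue_group_of=pd.Series(d["tissue_group_of"]),
        )


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # one global seed; deterministic sub-stream per operation
    return np.random.default_rng([config.seed, stream])


def generate_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Build the latent log-expression surface and artifact assignments.

    Latent log expression is gene baseline + module loading x tissue factor
    (+ N(0, noise_sd) gene/tissue noise).  Tissue factors are drawn once per
    tissue group per module, so grouped tissues share values and genes of one
    module are perfectly correlated in the noise-free limit (positive
    loadings make each profile an increasing affine map of the shared
    factor).
    """
    cfg = config
    rng = _rng(cfg, 0)
    genes = pd.Index([f"g{i:05d}" for i in range(cfg.n_genes)], name="gene")
    tissues = [f"tissue{j + 1:02d}" for j in range(cfg.n_tissues)]

    baseline = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
    lo_kb, hi_kb = cfg.transcript_length_range_kb
    lengths = np.exp(rng.uniform(np.log(lo_kb), np.log(hi_kb), cfg.n_genes))

    # tissue -> group map (-1 for ungrouped tissues)
    group_of = np.full(cfg.n_tissues, -1, dtype=int)
    for gid, members in enumerate(cfg.tissue_groups):
        for t in members:
            group_of[t] = gid

    # per-module tissue factors, shared within groups
    factors = np.empty((cfg.n_modules, cfg.n_tissues))
    for mid in range(cfg.n_modules):
        group_vals = rng.normal(0.0, cfg.factor_sd, len(cfg.tissue_groups))
        for t in range(cfg.n_tissues):
            if group_of[t] >= 0:
                factors[mid, t] = group_vals[group_of[t]]
            else:
                factors[mid, t] = rng.normal(0.0, cfg.factor_sd)

    sizes = rng.integers(cfg.module_size_range[0], cfg.module_size_range[1] + 1,
                         cfg.n_modules)
    if sizes.sum() > cfg.n_genes:
        raise SizingError(
            f"module sizes total {sizes.sum()} but only {cfg.n_genes} genes")
    order = rng.permutation(cfg.n_genes)
    module_of = np.full(cfg.n_genes, -1, dtype=int)
    pos = 0
    for mid, s in enumerate(sizes):
        module_of[order[pos:pos + s]] = mid
        pos += s

    # artifact genes drawn from disjoint pools so truth sets do not overlap
    artifact_order = rng.permutation(cfg.n_genes)
    n_sat = int(round(cfg.frac_saturated * cfg.n_genes))
    n_low = int(round(cfg.frac_low_expressed * cfg.n_genes))
    n_pairs = int(round(cfg.paralog_fraction * cfg.n_genes / 2))
    if n_sat + n_low + 2 * n_pairs > cfg.n_genes:
        raise SizingError("artifact fractions exceed the gene universe")
    sat_idx = artifact_order[:n_sat]
    low_idx = artifact_order[n_sat:n_sat + n_low]
    par_idx = artifact_order[n_sat + n_low:n_sat + n_low + 2 * n_pairs]

    # paralog members get their own moderate baseline so that peak
    # expression (baseline + boost + contrast) stays inside the array's
    # measurable range instead of clipping at the ceiling
    if len(par_idx):
        pb_mean, pb_sd = cfg.paralog_baseline
        baseline[par_idx] = rng.normal(pb_mean, pb_sd, len(par_idx))

    loadings = rng.uniform(*cfg.loading_range, cfg.n_genes)
    # each module gene may also load on a secondary module (genes belong to
    # more than one regulatory program), which keeps within-module
    # correlations below 1 even in the noise-free limit of the primary factor
    secondary = rng.integers(0, cfg.n_modules, cfg.n_genes)
    sec_weight = rng.uniform(0.0, cfg.module_mixing, cfg.n_genes)
    latent = baseline[:, None] + cfg.noise_sd * rng.standard_normal(
        (cfg.n_genes, cfg.n_tissues))
    in_mod = module_of >= 0
    latent[in_mod] += loadings[in_mod, None] * factors[module_of[in_mod]]
    if cfg.module_mixing > 0:
        mix = in_mod & (secondary != module_of)
        latent[mix] += (loadings[mix] * sec_weight[mix])[:, None] \
            * factors[secondary[mix]]

    # saturated genes: the whole profile is shifted up so the k-th highest
    # tissue sits just above the array ceiling -- the top k tissues clip
    # while the profile shape (and the RNA-Seq view of it) is preserved
    lat_sat = np.log(1.05 * (cfg.saturation_ceiling - cfg.background_floor)
                     / cfg.intensity_scale)
    k_sat = min(cfg.n_saturated_tissues, cfg.n_tissues)
    for g in sat_idx:
        kth_highest = np.sort(latent[g])[::-1][k_sat - 1]
        latent[g] += (lat_sat + 0.1) - kth_highest

    # paralog pairs: each member is tissue-specific for one tissue group
    # (pairs whose members prefer different groups emulate the
    # endosperm-specific / leaf-specific duplicate scenario).  The first
    # member is the abundant copy (storage-protein style), so its
    # cross-hybridization can swamp the quiet member's probes.
    n_groups = len(cfg.tissue_groups)
    preferred = {}
    for gi in par_idx:
        if n_groups > 0:
            grp = int(rng.integers(0, n_groups))
            members = list(cfg.tissue_groups[grp])
        else:
            grp = -1
            members = sorted(rng.choice(cfg.n_tissues,
                                        max(1, cfg.n_tissues // 3),
                                        replace=False))
        preferred[genes[gi]] = grp
        latent[gi, members] += cfg.paralog_contrast

    pairs = []
    classes = list(MISMATCH_CLASSES)
    for k in range(n_pairs):
        ia, ib = par_idx[2 * k], par_idx[2 * k + 1]
        latent[ia] += cfg.paralog_partner_boost
        pairs.append((genes[ia], genes[ib], classes[k % len(classes)]))

    saturated = set(genes[sat_idx])
    low = set(genes[low_idx])
    # bleed corrupts a profile only where the partner's contrasting signal
    # dominates the gene's own: the quiet member of a cross-hybridizing pair
    # whose members prefer different tissue groups
    bleed_affected = {b for a, b, cls in pairs
                      if cfg.paralog_bleed.get(cls, 0.0) > 0
                      and preferred.get(a) != preferred.get(b)}
    divergent = saturated | low | bleed_affected

    return SyntheticTruth(
        latent_log_expression=pd.DataFrame(latent, index=genes, columns=tissues),
        module_of_gene=pd.Series(module_of, index=genes),
        paralog_pairs=pairs,
        saturated_genes=saturated,
        low_count_genes=low,
        divergent_genes=divergent,
        transcript_length_kb=pd.Series(lengths, index=genes),
        tissue_group_of=pd.Series(group_of, index=tissues),
    )


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative-binomial draw parameterized by mean and dispersion alpha
    (variance = mu + alpha mu^2)."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_rnaseq(truth: SyntheticTruth, config: SyntheticConfig) -> ExpressionMatrix:
    """Draw negative-binomial counts per replicate and convert to FPKM.

    Expected fragment counts are proportional to sequencing depth x molar
    abundance x transcript length, so FPKM (1e6 * count / (total counts *
    length in kb)) recovers the latent abundance while short transcripts
    suffer more counting noise.  Genes in ``low_count_genes`` sit below the
    platform's detection limit: their expected count is a flat
    ``low_count_mean`` per replicate in every tissue, leaving most tissues
    at zero counts and the rest with uninformative singleton spikes.
    """
    cfg = config
    rng = _rng(cfg, 1)
    latent = truth.latent_log_expression.to_numpy()
    lengths = truth.transcript_length_kb.to_numpy()
    depths = cfg.depths

    abundance = np.exp(latent) * lengths[:, None]
    share = abundance / abundance.sum(axis=0, keepdims=True)
    mean_counts = share * depths[None, :]

    # below the detection limit the capture rate is background-dominated:
    # low genes get a flat mean of low_count_mean fragments per replicate,
    # so their counts are sampling noise with no profile information
    low_mask = truth.gene_ids.isin(truth.low_count_genes)
    if low_mask.any():
        mean_counts[low_mask] = cfg.low_count_mean

    cols, blocks = [], []
    for t_i, tissue in enumerate(truth.tissue_ids):
        for r in range(1, cfg.n_replicates + 1):
            counts = _nb_sample(rng, mean_counts[:, t_i], cfg.nb_dispersion)
            total = counts.sum()
            if total == 0:
                fpkm = np.zeros_like(counts, dtype=float)
            else:
                fpkm = 1e6 * counts / (total * lengths)
            cols.append((tissue, r))
            blocks.append(fpkm)
    values = pd.DataFrame(
        np.column_stack(blocks), index=truth.gene_ids,
        columns=pd.MultiIndex.from_tuples(cols, names=["tissue", "replicate"]))
    return ExpressionMatrix(values=values, platform="rnaseq", units="FPKM")


def simulate_microarray(truth: SyntheticTruth, config: SyntheticConfig) -> ExpressionMatrix:
    """Hybridization intensities with floor, paralog bleed and saturation.

    intensity = min(ceiling, floor + scale * exp(latent)
                    + sum over paralog partners of bleed * scale * exp(partner))
    then multiplied per replicate by log-normal noise exp(N(0, noise_sd)).
    """
    cfg = config
    rng = _rng(cfg, 2)
    latent = truth.latent_log_expression.to_numpy()
    signal = cfg.intensity_scale * np.exp(latent)

    bled = signal.copy()
    pos = {g: i for i, g in enumerate(truth.gene_ids)}
    for a, b, cls in truth.paralog_pairs:
        c = cfg.paralog_bleed.get(cls, 0.0)
        if c > 0:
            bled[pos[a]] += c * signal[pos[b]]
            bled[pos[b]] += c * signal[pos[a]]

    mean_intensity = np.minimum(cfg.saturation_ceiling,
                                cfg.background_floor + bled)

    cols, blocks = [], []
    for t_i, tissue in enumerate(truth.tissue_ids):
        for r in range(1, cfg.n_replicates + 1):
            noise = np.exp(rng.normal(0.0, cfg.noise_sd, latent.shape[0])) \
                if cfg.noise_sd > 0 else 1.0
            cols.append((tissue, r))
            blocks.append(mean_intensity[:, t_i] * noise)
    values = pd.DataFrame(
        np.column_stack(blocks), index=truth.gene_ids,
        columns=pd.MultiIndex.from_tuples(cols, names=["tissue", "replicate"]))
    return ExpressionMatrix(values=values, platform="microarray", units="intensity")


def write_synthetic_dataset(config: SyntheticConfig, outdir) -> dict:
    """Generate and write both platform tables plus the truth sidecar.

    Returns a dict of the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(config)
    rnaseq = simulate_rnaseq(truth, config)
    microarray = simulate_microarray(truth, config)
    paths = {
        "rnaseq": outdir / "rnaseq_fpkm.tsv",
        "microarray": outdir / "microarray_intensity.tsv",
        "truth": outdir / "truth.json",
        "paralogs": outdir / "paralog_pairs.tsv",
    }
    write_expression_table(rnaseq, paths["rnaseq"])
    write_expression_table(microarray, paths["microarray"])
    truth.to_json(paths["truth"])
    with open(paths["paralogs"], "w") as fh:
        fh.write("gene_a\tgene_b\tmismatch_class\n")
        for a, b, cls in truth.paralog_pairs:
            fh.write(f"{a}\t{b}\t{cls}\n")
    return {k: str(v) for k, v in paths.items()}
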