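"""Synthetic multi-omic brain cohorts with ground-truth subtype structure.

The generator emulates the data a post-mortem multi-omic ASD study feeds
into subtype discovery: four feature-by-sample layers (mRNA, miRNA,
promoter methylation, H3K27ac), paired frontal/temporal samples per
subject, nuisance covariates with realistic confounding, per-layer
missingness, and a toy genome tying features to genes, CpG probes, peaks,
eSNPs and chromatin contacts.

Two latent ASD subtypes are planted: "convergent" subjects carry a shared
latent severity score propagated (with configurable cross-layer
correlation) into the truly differential features of all four layers;
"disparate" subjects and controls carry no signal.  Methylation is emitted
on the beta scale through a logistic squash of the latent Gaussian values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic import GenomeAnnotation, promoter_interval, GenomicInterval

__all__ = ["CohortConfig", "TrueLabels", "CohortBundle",
           "generate_cohort", "generate_annotations"]

LAYERS = ("mrna", "mirna", "meth", "acetyl")

# availability patterns that never occur in the emulated study design:
# miRNA-only and the miRNA/methylation/acetylation triple
_FORBIDDEN_PATTERNS = {("mirna",), ("mirna", "meth", "acetyl"), ()}


def _default_counts() -> dict[str, int]:
    return {"mrna": 600, "mirna": 150, "meth": 400, "acetyl": 500}


def _default_diff() -> dict[str, int]:
    return {"mrna": 60, "mirna": 20, "meth": 40, "acetyl": 50}


def _default_effects() -> dict[str, float]:
    return {l: 2.0 for l in LAYERS}


def _default_missing() -> dict[str, float]:
    return {l: 0.15 for l in LAYERS}


def _default_cov_effects() -> dict[str, float]:
    return {"age": 0.2, "sex": 0.3, "region": 0.3, "batch": 0.3,
            "bank": 0.2, "rin": 0.3, "cet": 0.4, "pmi": 0.2}


# Each nuisance covariate perturbs the layers whose differential model
# adjusts for it (expression models carry RIN/batch/sequencing covariates,
# epigenomic models carry cell-type proportion).  Residual confounding by
# covariates a model omits is a feature of real data this generator leaves
# out deliberately, so planted null features are genuinely null.
LAYER_COVARIATES: dict[str, tuple[str, ...]] = {
    "mrna": ("age", "sex", "region", "batch", "bank", "rin"),
    "mirna": ("age", "sex", "region", "bank", "rin", "pmi"),
    "meth": ("age", "sex", "region", "batch", "bank", "cet"),
    "acetyl": ("age", "sex", "region", "bank", "cet"),
}


@dataclass
class CohortConfig:
    """Study-condition knobs for the synthetic cohort.

    Subject counts default to the fully observed reference cohort of the
    emulated study design (30 ASD, 17 control subjects); two thirds of ASD
    subjects are convergent.  Effect sizes are standardized mean shifts of
    the truly differential features in residual-SD units.
    """

    n_subjects_asd: int = 30
    n_subjects_control: int = 17
    p_paired_regions: float = 0.85
    frac_convergent: float = 2.0 / 3.0
    frac_region_discordant: float = 0.0   # of convergent paired subjects
    n_features: dict[str, int] = field(default_factory=_default_counts)
    n_diff_features: dict[str, int] = field(default_factory=_default_diff)
    effect_size: dict[str, float] = field(default_factory=_default_effects)
    cross_layer_loading_corr: float = 0.9
    severity_sd: float = 0.2              # spread of the latent severity
    subject_intercept_sd: float = 0.4     # brain-ID random effect
    covariate_effect_sizes: dict[str, float] = field(
        default_factory=_default_cov_effects)
    missingness_pattern: dict[str, float] = field(default_factory=_default_missing)
    # toy genome
    gene_spacing: int = 20_000
    probes_per_promoter_mean: float = 3.0
    probes_per_promoter_min: int = 0
    probes_per_genebody_mean: float = 4.0
    frac_promoter_peaks: float = 0.3
    frac_eqtl_peaks: float = 0.3
    frac_hic_peaks: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (("p_paired_regions", self.p_paired_regions),
                        ("frac_convergent", self.frac_convergent),
                        ("frac_region_discordant", self.frac_region_discordant),
                        ("cross_layer_loading_corr", self.cross_layer_loading_corr),
                        ("frac_promoter_peaks", self.frac_promoter_peaks),
                        ("frac_eqtl_peaks", self.frac_eqtl_peaks),
                        ("frac_hic_peaks", self.frac_hic_peaks)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for p in self.missingness_pattern.values():
            if not (0.0 <= p <= 1.0):
                raise ValueError("missingness probabilities must lie in [0, 1]")
        for layer in LAYERS:
            if self.n_diff_features[layer] > self.n_features[layer]:
                raise ValueError(f"n_diff_features > n_features for {layer}")
            if not math.isfinite(self.effect_size[layer]):
                raise ValueError("effect sizes must be finite")
        if self.n_subjects_asd < 1 or self.n_subjects_control < 1:
            raise ValueError("need at least one subject per diagnosis")

    @property
    def n_convergent(self) -> int:
        """Convergent ASD subject count: round(frac * n), ties to even."""
        return round(self.frac_convergent * self.n_subjects_asd)


@dataclass
class TrueLabels:
    subject_subtype: pd.Series     # subject -> convergent|disparate|control
    sample_subtype: pd.Series      # sample  -> convergent|disparate|control
    diff_features: dict[str, pd.Series]  # layer -> signed effects per feature


@dataclass
class CohortBundle:
    layers: dict[str, pd.DataFrame]      # observed samples only, per layer
    metadata: pd.DataFrame               # all samples
    truth: TrueLabels
    annotation: GenomeAnnotation
    observed: dict[str, list[str]]       # layer -> observed sample ids
    config: CohortConfig

    def complete_samples(self) -> list[str]:
        """Samples observed in all four layers (the fused-network set)."""
        sets = [set(v) for v in self.observed.values()]
        common = set.intersection(*sets)
        return [s for s in self.metadata.index if s in common]


# ---------------------------------------------------------------------------
# Toy genome


def generate_annotations(config: CohortConfig) -> GenomeAnnotation:
    """Toy single-chromosome genome coherent with the cohort layers.

    Genes tile "chrT" at ``gene_spacing`` intervals with random strand and
    lengths; CpG probes land in promoters and gene bodies with Poisson
    counts; H3K27ac peaks split into promoter-resident and distal peaks; a
    fraction of distal peaks carry an eSNP or a significant (FDR < 1%)
    contact to a promoter within 1 Mb.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng([config.seed, 101])
    n_genes = config.n_features["mrna"]
    chrom = "chrT"
    spacing = config.gene_spacing

    genes = []
    for i in range(n_genes):
        anchor = (i + 1) * spacing
        length = int(rng.integers(4000, 12000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((f"gene_{i:04d}", chrom, anchor, anchor + length, strand,
                      f"Gene{i}"))
    genes_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end",
                                            "strand", "name"])

    gene_iv = [GenomicInterval(r.chrom, r.start, r.end, r.strand, r.gene_id)
               for r in genes_df.itertuples()]
    promoters = {g.id: promoter_interval(g) for g in gene_iv}

    probes = []
    k = 0
    for g in gene_iv:
        prom = promoters[g.id]
        n_prom_probes = config.probes_per_promoter_min + rng.poisson(
            max(0.0, config.probes_per_promoter_mean
                - config.probes_per_promoter_min))
        for _ in range(n_prom_probes):
            pos = int(rng.integers(prom.start, prom.end))
            probes.append((f"cg{k:06d}", chrom, pos))
            k += 1
        for _ in range(rng.poisson(config.probes_per_genebody_mean)):
            pos = int(rng.integers(g.start, g.end))
            probes.append((f"cg{k:06d}", chrom, pos))
            k += 1
    probes_df = pd.DataFrame(probes, columns=["probe_id", "chrom", "pos"])

    n_peaks = config.n_features["acetyl"]
    n_prom_peaks = int(round(config.frac_promoter_peaks * n_peaks))
    prom_genes = rng.choice(n_genes, size=n_prom_peaks, replace=False)
    peaks = []
    for j in range(n_peaks):
        if j < n_prom_peaks:
            prom = promoters[f"gene_{prom_genes[j]:04d}"]
            centre = int(rng.integers(prom.start + 200, prom.end - 200))
        else:
            # intergenic: between gene end and next promoter, away from 2 kb
            # upstream windows
            gi = int(rng.integers(0, n_genes - 1))
            lo = genes_df.loc[gi, "end"] + 2500
            hi = (gi + 2) * spacing - 2500
            centre = int(rng.integers(lo, max(lo + 1, hi)))
        half = int(rng.integers(150, 600))
        peaks.append((f"peak_{j:04d}", chrom, max(0, centre - half), centre + half))
    peaks_df = pd.DataFrame(peaks, columns=["peak_id", "chrom", "start", "end"])

    # eSNPs inside a fraction of distal peaks, each linked to a gene < 1 Mb
    starts = genes_df["start"].to_numpy()
    ends = genes_df["end"].to_numpy()
    strands = genes_df["strand"].to_numpy()
    tss = np.where(strands == "+", starts, ends)
    eqtl_rows = []
    s = 0
    for j in range(n_prom_peaks, n_peaks):
        if rng.random() >= config.frac_eqtl_peaks:
            continue
        pk = peaks_df.iloc[j]
        mid = 0.5 * (pk["start"] + pk["end"])
        near = np.flatnonzero(np.abs(tss - mid) <= 1_000_000)
        if len(near) == 0:
            continue
        gid = genes_df.loc[int(rng.choice(near)), "gene_id"]
        pos = int(rng.integers(pk["start"], pk["end"]))
        eqtl_rows.append((f"rs{s:06d}", chrom, pos, gid))
        s += 1
    eqtl_df = pd.DataFrame(eqtl_rows, columns=["snp_id", "chrom", "pos", "gene_id"])

    hic_rows = []
    for j in range(n_prom_peaks, n_peaks):
        if rng.random() >= config.frac_hic_peaks:
            continue
        pk = peaks_df.iloc[j]
        mid = 0.5 * (pk["start"] + pk["end"])
        near = np.flatnonzero(np.abs(tss - mid) <= 1_000_000)
        if len(near) == 0:
            continue
        gi = int(rng.choice(near))
        prom = promoters[genes_df.loc[gi, "gene_id"]]
        fdr = float(rng.uniform(0.0, 0.009))
        hic_rows.append((chrom, int(pk["start"]) - 100, int(pk["end"]) + 100,
                         chrom, prom.start, prom.end, fdr))
    # some non-significant decoy contacts
    for _ in range(max(5, n_peaks // 20)):
        a = int(rng.integers(0, n_genes * spacing))
        b = int(rng.integers(0, n_genes * spacing))
        hic_rows.append((chrom, a, a + 2000, chrom, b, b + 2000,
                         float(rng.uniform(0.05, 0.9))))
    hic_df = pd.DataFrame(hic_rows, columns=["chromA", "startA", "endA",
                                             "chromB", "startB", "endB", "fdr"])
    return GenomeAnnotation(genes=genes_df, probes=probes_df, peaks=peaks_df,
                            eqtl_pairs=eqtl_df, hic_contacts=hic_df)


# ---------------------------------------------------------------------------
# Cohort


def _draw_labels(config: CohortConfig, rng: np.random.Generator) -> pd.Series:
    subjects = ([f"asd_{i:03d}" for i in range(config.n_subjects_asd)]
                + [f"ctl_{i:03d}" for i in range(config.n_subjects_control)])
    conv_idx = rng.choice(config.n_subjects_asd, size=config.n_convergent,
                          replace=False)
    sub = pd.Series("control", index=subjects, name="subject_subtype")
    sub.iloc[: config.n_subjects_asd] = "disparate"
    sub.iloc[conv_idx] = "convergent"
    return sub


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Draw a full synthetic cohort; byte-identical for a fixed seed."""
    rng = np.random.default_rng([config.seed, 7])
    annotation = generate_annotations(config)
    subject_subtype = _draw_labels(config, rng)
    subjects = subject_subtype.index.tolist()

    # --- samples & per-sample covariates
    rows = []
    sample_carries: dict[str, bool] = {}
    for subj in subjects:
        paired = rng.random() < config.p_paired_regions
        regions = ["frontal", "temporal"] if paired \
            else [["frontal", "temporal"][int(rng.integers(0, 2))]]
        subtype = subject_subtype[subj]
        discordant = (subtype == "convergent" and paired
                      and rng.random() < config.frac_region_discordant)
        silent_region = regions[int(rng.integers(0, 2))] if discordant else None
        age = float(rng.uniform(5, 60))
        sex = "M" if rng.random() < 0.7 else "F"
        bank = "bankA" if rng.random() < 0.5 else "bankB"
        for reg in regions:
            sid = f"{subj}_{reg[0].upper()}"
            carries = subtype == "convergent" and reg != silent_region
            sample_carries[sid] = carries
            rows.append({
                "sample_id": sid, "brain_id": subj,
                "diagnosis": "ASD" if subj.startswith("asd") else "control",
                "region": reg, "age": age, "sex": sex, "bank": bank,
                "batch": f"b{int(rng.integers(1, 4))}",
                "rin": float(np.clip(rng.normal(7.0, 1.0), 3.0, 10.0)),
                "pmi": float(np.clip(rng.normal(15.0, 5.0), 1.0, 40.0)),
                "cet": float(np.clip(rng.normal(0.3, 0.08), 0.05, 0.6)),
                "seq_pc1": float(rng.normal()),
            })
    metadata = pd.DataFrame(rows).set_index("sample_id")
    metadata["sample_subtype"] = [
        "control" if metadata.loc[s, "diagnosis"] == "control"
        else ("convergent" if sample_carries[s] else "disparate")
        for s in metadata.index
    ]
    samples = metadata.index.tolist()
    n_samples = len(samples)

    # --- latent severity, shared across layers with configurable coupling
    z_subject = pd.Series(rng.normal(1.0, config.severity_sd, len(subjects)),
                          index=subjects)
    rho = config.cross_layer_loading_corr
    layer_sev = {}
    for layer in LAYERS:
        noise = rng.normal(0.0, config.severity_sd, len(subjects))
        layer_sev[layer] = 1.0 + rho * (z_subject.to_numpy() - 1.0) \
            + math.sqrt(max(0.0, 1.0 - rho**2)) * noise
    carrier = np.array([sample_carries[s] for s in samples], float)
    subj_of_sample = metadata["brain_id"].to_numpy()
    subj_idx = pd.Index(subjects).get_indexer(subj_of_sample)

    # --- standardized covariate matrix for injection
    cov_cols = {}
    for cov in config.covariate_effect_sizes:
        v = metadata[cov] if cov in metadata.columns else None
        if v is None:
            continue
        if v.dtype == object:
            levels = sorted(v.unique())
            x = (v == levels[-1]).to_numpy(float)
        else:
            x = v.to_numpy(float)
        sd = x.std()
        cov_cols[cov] = (x - x.mean()) / (sd if sd > 0 else 1.0)
    cov_mat = np.column_stack(list(cov_cols.values())) if cov_cols \
        else np.zeros((n_samples, 0))
    cov_gammas = np.array([config.covariate_effect_sizes[c] for c in cov_cols])

    # --- feature ids per layer, tied to the toy genome
    feature_ids = {
        "mrna": annotation.genes["gene_id"].tolist(),
        "mirna": [f"mir_{i:04d}" for i in range(config.n_features["mirna"])],
        "meth": annotation.genes["gene_id"].tolist()[: config.n_features["meth"]],
        "acetyl": annotation.peaks["peak_id"].tolist(),
    }

    # differential features; promoter peaks of differential genes are made
    # differential with the SAME sign so promoter-linked acetylation and
    # expression changes are positively coupled
    diff_sets: dict[str, pd.Series] = {}
    mrna_ids = feature_ids["mrna"]
    d_mrna = rng.choice(len(mrna_ids), size=config.n_diff_features["mrna"],
                        replace=False)
    signs_mrna = rng.choice([-1.0, 1.0], size=len(d_mrna))
    diff_sets["mrna"] = pd.Series(signs_mrna,
                                  index=[mrna_ids[i] for i in d_mrna])

    # map promoter peaks -> gene (peak centre inside the gene's promoter)
    g_start = annotation.genes["start"].to_numpy()
    g_end = annotation.genes["end"].to_numpy()
    g_plus = (annotation.genes["strand"] == "+").to_numpy()
    g_tss = np.where(g_plus, g_start, g_end)
    prom_lo = np.where(g_plus, g_tss - 2000, g_tss)
    prom_hi = np.where(g_plus, g_tss, g_tss + 2000)
    gene_id_arr = annotation.genes["gene_id"].to_numpy()
    prom_peak_gene = {}
    for pk in annotation.peaks.itertuples():
        mid = 0.5 * (pk.start + pk.end)
        hit = np.flatnonzero((prom_lo <= mid) & (mid < prom_hi))
        if len(hit):
            prom_peak_gene[pk.peak_id] = gene_id_arr[hit[0]]
    coupled = {pk: g for pk, g in prom_peak_gene.items()
               if g in diff_sets["mrna"].index}
    acetyl_ids = feature_ids["acetyl"]
    quota = config.n_diff_features["acetyl"]
    chosen = list(coupled)[:quota]
    acetyl_signs = {pk: float(diff_sets["mrna"][coupled[pk]]) for pk in chosen}
    remaining = [p for p in acetyl_ids if p not in acetyl_signs]
    extra = rng.choice(len(remaining), size=quota - len(chosen), replace=False)
    for i in extra:
        acetyl_signs[remaining[i]] = float(rng.choice([-1.0, 1.0]))
    diff_sets["acetyl"] = pd.Series(acetyl_signs)

    for layer in ("mirna", "meth"):
        ids = feature_ids[layer]
        d = rng.choice(len(ids), size=config.n_diff_features[layer], replace=False)
        diff_sets[layer] = pd.Series(rng.choice([-1.0, 1.0], size=len(d)),
                                     index=[ids[i] for i in d])

    # --- layer matrices
    cov_names = list(cov_cols)
    layers_full: dict[str, pd.DataFrame] = {}
    for layer in LAYERS:
        ids = feature_ids[layer]
        p = len(ids)
        baseline = rng.uniform(-2.0, 2.0, p) if layer == "meth" \
            else rng.normal(5.0, 2.0, p)
        active = np.array([c in LAYER_COVARIATES[layer] for c in cov_names],
                          float)
        load = rng.normal(0.0, 1.0, (p, cov_mat.shape[1])) * cov_gammas * active
        subj_int = rng.normal(0.0, config.subject_intercept_sd,
                              (p, len(subjects)))
        noise = rng.normal(0.0, 1.0, (p, n_samples))
        X = (baseline[:, None] + load @ cov_mat.T
             + subj_int[:, subj_idx] + noise)
        sev = layer_sev[layer][subj_idx] * carrier
        eff = config.effect_size[layer]
        dser = diff_sets[layer]
        pos = pd.Index(ids).get_indexer(dser.index)
        X[pos] += eff * dser.to_numpy()[:, None] * sev[None, :]
        if layer == "meth":
            X = 1.0 / (1.0 + np.exp(-X))
        layers_full[layer] = pd.DataFrame(X, index=ids, columns=samples)

    # --- missingness: redraw per sample until the availability pattern is
    # one the study design permits (never miRNA-only / mirna+meth+acetyl /
    # fully unobserved)
    miss_p = np.array([config.missingness_pattern[l] for l in LAYERS])
    observed: dict[str, list[str]] = {l: [] for l in LAYERS}
    for s in samples:
        for _ in range(1000):
            obs = rng.random(4) >= miss_p
            pattern = tuple(l for l, o in zip(LAYERS, obs) if o)
            if pattern not in _FORBIDDEN_PATTERNS:
                break
        else:
            raise ValueError(
                "missingness_pattern makes every draw an unobservable "
                "availability pattern; layer "
                f"probabilities {config.missingness_pattern} admit no "
                "classifiable sample")
        for l, o in zip(LAYERS, obs):
            if o:
                observed[l].append(s)

    for layer in LAYERS:
        obs_meta = metadata.loc[observed[layer]]
        counts = obs_meta["diagnosis"].value_counts()
        if counts.get("ASD", 0) == 0 or counts.get("control", 0) == 0:
            raise ValueError(
                f"layer {layer!r} would have 0 observed samples in one "
                "diagnosis group; lower missingness or enlarge the cohort")

    layers_obs = {l: layers_full[l][observed[l]] for l in LAYERS}
    truth = TrueLabels(subject_subtype=subject_subtype,
                       sample_subtype=metadata["sample_subtype"].copy(),
                       diff_features=diff_sets)
    return CohortBundle(layers=layers_obs, metadata=metadata, truth=truth,
                        annotation=annotation, observed=observed, config=config)


# ---------------------------------------------------------------------------
# Plain-text export


def write_bundle(bundle: CohortBundle, outdir) -> None:
    """Write layers, metadata, truth and the toy genome as TSV/BED files."""
    from pathlib import Path
    from .genomic import write_bed, write_gene_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for layer, mat in bundle.layers.items():
        mat.to_csv(out / f"{layer}.tsv", sep="\t")
    bundle.metadata.to_csv(out / "metadata.tsv", sep="\t")
    truth = pd.DataFrame({"sample_subtype": bundle.truth.sample_subtype})
    truth.to_csv(out / "truth.tsv", sep="\t")
    write_gene_table(bundle.annotation.genes, out / "genes.tsv")
    probes = bundle.annotation.probes
    bed = pd.DataFrame({"chrom": probes["chrom"], "start": probes["pos"],
                        "end": probes["pos"] + 1, "name": probes["probe_id"],
                        "score": 0, "strand": "."})
    write_bed(bed, out / "probes.bed")
    pk = bundle.annotation.peaks
    write_bed(pd.DataFrame({"chrom": pk["chrom"], "start": pk["start"],
                            "end": pk["end"], "name": pk["peak_id"],
                            "score": 0, "strand": "."}), out / "peaks.bed")
    bundle.annotation.eqtl_pairs.to_csv(out / "eqtl.tsv", sep="\t", index=False)
    bundle.annotation.hic_contacts.to_csv(out / "hic.tsv", sep="\t", index=False)
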