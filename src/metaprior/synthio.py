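"""Synthetic multi-study, multi-omics data with known ground truth.

Emulates the shape of an ER-negative vs ER-positive breast-tumor compendium:
several transcriptomics cohorts with partially overlapping gene panels, one
cohort that additionally carries proteomics (with missing observations) and
metabolomics, a planted fraction of truly differential features shared across
cohorts, and annotation fixtures (gene->EC map, pathway sets, compound
fingerprints and reactant pairs, per-gene literature counts) whose ground
truth is returned alongside the data.

Abundances are log2-normal per feature: a feature f measured in sample s of
group g has log2 value ``mu_f + delta_f * I[g == ERneg] + sigma * eps`` with
``delta_f = +/- effect_size * sigma`` for differential features and 0
otherwise. Literature counts are drawn independently of differential status,
so significant-but-under-studied genes exist by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ERNEG = "ERneg"
ERPOS = "ERpos"
PLATFORMS = ("transcript", "protein", "metabolite")

# small-molecule EC numbers drawn from common intermediary metabolism,
# including 1.1.1.14 (sorbitol dehydrogenase)
_RETAINED_EC_POOL = [
    "1.1.1.14", "1.1.1.27", "1.1.1.37", "1.1.1.42", "1.1.1.44", "1.1.1.49",
    "1.2.1.12", "1.4.1.3", "1.8.1.7", "1.15.1.1",
    "2.1.1.2", "2.2.1.1", "2.3.1.85", "2.4.1.1", "2.5.1.18", "2.6.1.1",
    "2.7.1.1", "2.7.1.11", "2.7.1.40", "2.7.4.3",
    "3.1.3.11", "3.2.1.20", "3.5.1.1", "3.6.1.9",
    "4.1.1.32", "4.1.2.13", "4.2.1.2", "4.2.1.11",
    "5.3.1.6", "5.3.1.9", "5.4.2.2",
    "6.2.1.3", "6.3.4.5",
]
# enzymes whose substrates are proteins or nucleic acids (excluded classes)
_EXCLUDED_EC_POOL = [
    "2.7.11.1", "2.7.10.1", "2.7.12.2", "2.7.13.3",
    "3.4.21.5", "3.4.24.7",
    "2.7.7.6", "2.7.7.7", "2.7.7.49",
    "5.6.2.1", "6.1.1.4", "3.1.26.3", "3.6.4.12", "2.3.2.27",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic compendium.

    Defaults emulate a ten-study design with 30 vs 30 samples per group,
    10% truly differential genes at a one-standard-deviation log2 effect,
    80% per-study panel coverage and 10% proteomics missingness.
    """

    n_studies: int = 10
    n_genes: int = 1000
    n_proteins: int = 200
    n_metabolites: int = 100
    n_neg: int = 30
    n_pos: int = 30
    frac_diff: float = 0.10
    effect_size: float = 1.0
    sigma: float = 1.0
    panel_overlap: float = 0.8
    missing_rate: float = 0.10
    mnar: bool = False
    effect_jitter: float = 0.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    metabolic_fraction: float = 0.10
    excluded_fraction: float = 0.05
    n_pathways: int = 25
    fingerprint_bits: int = 128
    fingerprint_density: float = 0.2
    lit_mean: float = 25.0
    lit_dispersion: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_studies", "n_genes", "n_proteins", "n_metabolites",
                     "n_neg", "n_pos", "n_pathways", "fingerprint_bits"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("frac_diff", "panel_overlap", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.panel_overlap == 0.0:
            raise ValueError("panel_overlap must be in (0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_proteins > self.n_genes:
            raise ValueError("n_proteins cannot exceed n_genes: each protein "
                             "is encoded by a distinct gene")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class OmicsMatrix:
    """One study/platform's feature-by-sample abundances with group labels.

    ``values`` is a features x samples DataFrame of non-negative linear-scale
    abundances (NaN marks an absent observation, proteomics only); ``labels``
    maps each sample id to ERneg/ERpos.
    """

    values: pd.DataFrame
    labels: pd.Series
    platform: str
    study_id: str

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if not self.values.index.is_unique:
            raise ValueError("feature ids must be unique")
        missing = set(self.values.columns) - set(self.labels.index)
        if missing:
            raise ValueError(f"unlabeled samples: {sorted(missing)[:5]}")
        groups = set(self.labels.loc[list(self.values.columns)])
        if not {ERNEG, ERPOS} <= groups:
            raise ValueError("both ERneg and ERpos groups must be non-empty")

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == group]


@dataclass
class CompoundRecord:
    """A metabolite with a structural fingerprint and biochemical links."""

    compound_id: str
    fingerprint: np.ndarray  # uint8 0/1 vector, uniform length per dataset
    reactant_pairs: set[str] = field(default_factory=set)
    ec_links: set[str] = field(default_factory=set)


@dataclass
class AnnotationBundle:
    """Annotation fixtures plus the ground truth used to build them."""

    ec_map: pd.DataFrame              # columns: gene, ec
    pathways: dict[str, tuple[str, set[str]]]  # id -> (name, members)
    compounds: dict[str, CompoundRecord]
    lit_counts: pd.DataFrame          # columns: gene, n_papers
    protein_gene_map: pd.DataFrame    # columns: protein, gene
    true_metabolic_genes: set[str]    # genes carrying >=1 small-molecule EC


def _feature_ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def gene_ids(config: SimConfig) -> list[str]:
    return _feature_ids("G", config.n_genes)


def protein_ids(config: SimConfig) -> list[str]:
    return _feature_ids("P", config.n_proteins)


def metabolite_ids(config: SimConfig) -> list[str]:
    return _feature_ids("M", config.n_metabolites)


def _platform_code(platform: str) -> int:
    return PLATFORMS.index(platform)


def _n_features(config: SimConfig, platform: str) -> int:
    return {"transcript": config.n_genes, "protein": config.n_proteins,
            "metabolite": config.n_metabolites}[platform]


def _platform_ids(config: SimConfig, platform: str) -> list[str]:
    return {"transcript": gene_ids, "protein": protein_ids,
            "metabolite": metabolite_ids}[platform](config)


def make_truth(config: SimConfig, platform: str = "transcript") -> pd.DataFrame:
    """Shared per-feature ground truth for one platform.

    Proteins inherit the differential status of the gene they encode
    (protein ``Pk`` encodes gene ``Gk``), so the gene-level truth is the
    meta-analysis ground truth across all platforms.
    """
    if platform == "protein":
        gene_truth = make_truth(config, "transcript")
        ids = protein_ids(config)
        genes = gene_ids(config)[: config.n_proteins]
        tt = gene_truth.loc[genes].copy()
        tt.index = pd.Index(ids, name="feature")
        return tt
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, _platform_code(platform), 7)))
    ids = _platform_ids(config, platform)
    n = len(ids)
    is_diff = rng.random(n) < config.frac_diff
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    effect = np.where(is_diff, sign * config.effect_size * config.sigma, 0.0)
    return pd.DataFrame(
        {
            # a feature is differential only if it carries a nonzero effect,
            # so effect_size=0 yields a global null
            "is_differential": effect != 0.0,
            "true_direction": np.where(effect > 0, "up",
                                       np.where(effect < 0, "down", "none")),
            "true_log2_effect": effect,
        },
        index=pd.Index(ids, name="feature"),
    )


def _baselines(config: SimConfig, platform: str) -> np.ndarray:
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, _platform_code(platform), 11)))
    return config.baseline_mean + config.baseline_sd * rng.normal(
        size=_n_features(config, platform))


def simulate_study(config: SimConfig, platform: str = "transcript",
                   study_index: int = 0) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Simulate one study's abundance matrix for a platform.

    Returns the matrix together with the (platform-level, cross-study shared)
    truth table. The measured panel is a seeded random subset of the feature
    universe of size ``panel_overlap * n_features``; proteomics cells are
    dropped with probability ``missing_rate`` (uniformly if MCAR, biased
    towards low-abundance cells if ``mnar``).
    """
    if platform not in PLATFORMS:
        raise ValueError(f"unknown platform {platform!r}")
    if not 0 <= study_index < config.n_studies:
        raise ValueError("study_index out of range")
    if config.n_neg < 1 or config.n_pos < 1:
        raise ValueError("each group needs at least one sample")

    truth = make_truth(config, platform)
    mu = _baselines(config, platform)
    ids = list(truth.index)
    n_feat = len(ids)

    rng = np.random.default_rng(np.random.SeedSequence(
        (config.seed, _platform_code(platform), study_index + 101)))

    panel_size = max(1, int(round(config.panel_overlap * n_feat)))
    panel_idx = np.sort(rng.choice(n_feat, size=panel_size, replace=False))

    study_id = f"S{study_index:02d}"
    neg = [f"{study_id}_neg{j:02d}" for j in range(config.n_neg)]
    pos = [f"{study_id}_pos{j:02d}" for j in range(config.n_pos)]
    samples = neg + pos
    is_neg = np.array([1.0] * config.n_neg + [0.0] * config.n_pos)

    jitter = 1.0 + config.effect_jitter * rng.normal() if config.effect_jitter else 1.0
    delta = truth["true_log2_effect"].to_numpy()[panel_idx] * jitter
    base = mu[panel_idx]

    log2vals = (base[:, None] + delta[:, None] * is_neg[None, :]
                + config.sigma * rng.normal(size=(panel_size, len(samples))))
    vals = np.exp2(log2vals)

    if platform == "protein" and config.missing_rate > 0:
        if config.mnar:
            # low-abundance cells are up to twice as likely to be missing
            order = log2vals.ravel().argsort().argsort() / max(log2vals.size - 1, 1)
            p_miss = np.clip(config.missing_rate * 2.0 * (1.0 - order), 0, 1)
            mask = rng.random(log2vals.size) < p_miss
            vals.ravel()[mask] = np.nan
        else:
            mask = rng.random(vals.shape) < config.missing_rate
            vals[mask] = np.nan

    values = pd.DataFrame(vals, index=pd.Index([ids[i] for i in panel_idx],
                                               name="feature"),
                          columns=samples)
    labels = pd.Series([ERNEG] * config.n_neg + [ERPOS] * config.n_pos,
                       index=samples, name="group")
    return OmicsMatrix(values, labels, platform, study_id), truth


def simulate_collection(config: SimConfig, platform: str = "transcript"
                        ) -> tuple[list[OmicsMatrix], pd.DataFrame]:
    """Simulate ``n_studies`` studies sharing one truth table.

    Differential features and their directions are identical across studies
    (the meta-analysis assumes cross-study consistency); the measured panels
    differ per study.
    """
    matrices = []
    truth = make_truth(config, platform)
    for i in range(config.n_studies):
        m, _ = simulate_study(config, platform, i)
        matrices.append(m)
    return matrices, truth


def simulate_annotations(config: SimConfig) -> AnnotationBundle:
    """Generate EC map, pathway sets, compound records and literature counts.

    A ``metabolic_fraction`` of genes receive small-molecule EC numbers and a
    further ``excluded_fraction`` receive only protein/nucleic-acid-substrate
    EC numbers; a small subset of the metabolic genes additionally carry an
    excluded EC (mixed annotation). Pathways partition genes and metabolites.
    Literature counts are negative-binomial and independent of the truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 9, 99)))
    genes = gene_ids(config)
    mets = metabolite_ids(config)
    prots = protein_ids(config)
    n = config.n_genes

    n_metab = int(round(config.metabolic_fraction * n))
    n_excl = int(round(config.excluded_fraction * n))
    perm = rng.permutation(n)
    metab_genes = [genes[i] for i in sorted(perm[:n_metab])]
    excl_genes = [genes[i] for i in sorted(perm[n_metab:n_metab + n_excl])]

    rows = []
    for g in metab_genes:
        for ec in rng.choice(_RETAINED_EC_POOL,
                             size=rng.integers(1, 3), replace=False):
            rows.append((g, str(ec)))
    # every fifth metabolic gene also carries an excluded EC (mixed case)
    for g in metab_genes[::5]:
        rows.append((g, str(rng.choice(_EXCLUDED_EC_POOL))))
    for g in excl_genes:
        rows.append((g, str(rng.choice(_EXCLUDED_EC_POOL))))
    ec_map = pd.DataFrame(rows, columns=["gene", "ec"]).sort_values(
        ["gene", "ec"], ignore_index=True)

    # pathways partition the gene universe; metabolites are spread over them
    members_pool = list(genes)
    rng.shuffle(members_pool)
    cuts = np.linspace(0, n, config.n_pathways + 1).round().astype(int)
    pathways: dict[str, tuple[str, set[str]]] = {}
    for k in range(config.n_pathways):
        mem = set(members_pool[cuts[k]:cuts[k + 1]])
        if not mem:
            raise ValueError("pathway of size 0 requested; increase n_genes "
                             "or decrease n_pathways")
        pathways[f"PW{k:03d}"] = (f"Synthetic pathway {k}", mem)
    pw_ids = sorted(pathways)
    for j, m in enumerate(mets):
        pid = pw_ids[j % len(pw_ids)]
        pathways[pid][1].add(m)

    compounds: dict[str, CompoundRecord] = {}
    fp = (rng.random((len(mets), config.fingerprint_bits))
          < config.fingerprint_density).astype(np.uint8)
    for j, m in enumerate(mets):
        ecs = set(rng.choice(_RETAINED_EC_POOL,
                             size=rng.integers(0, 3), replace=False).tolist())
        compounds[m] = CompoundRecord(m, fp[j], set(), ecs)
    # reactant pairs: chain metabolites that share a pathway
    for pid in pw_ids:
        chain = sorted(m for m in pathways[pid][1] if m.startswith("M"))
        for a, b in zip(chain, chain[1:]):
            compounds[a].reactant_pairs.add(b)
            compounds[b].reactant_pairs.add(a)

    counts = rng.negative_binomial(
        config.lit_dispersion,
        config.lit_dispersion / (config.lit_dispersion + config.lit_mean),
        size=n)
    lit_counts = pd.DataFrame({"gene": genes, "n_papers": counts})

    pg = pd.DataFrame({"protein": prots, "gene": genes[: config.n_proteins]})
    return AnnotationBundle(ec_map, pathways, compounds, lit_counts, pg,
                            set(metab_genes))


# ---------------------------------------------------------------------------
# plain-text writers (TSV/GMT dialect shared by the whole pipeline)

def write_matrix_tsv(matrix: OmicsMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature",
                         float_format="%.6g")


def write_labels_tsv(matrix: OmicsMatrix, path: str | Path) -> None:
    matrix.labels.rename_axis("sample").to_frame().to_csv(path, sep="\t")


def read_matrix_tsv(matrix_path: str | Path, labels_path: str | Path,
                    platform: str, study_id: str = "S00") -> OmicsMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index.name = "feature"
    labels = pd.read_csv(labels_path, sep="\t", index_col=0)["group"]
    return OmicsMatrix(values, labels, platform, study_id)


def write_truth_tsv(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t")


def write_gmt(pathways: dict[str, tuple[str, set[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(pathways):
            name, members = pathways[pid]
            fh.write("\t".join([pid, name, *sorted(members)]) + "\n")


def write_ec_tsv(ec_map: pd.DataFrame, path: str | Path) -> None:
    ec_map.to_csv(path, sep="\t", index=False)


def write_fingerprints_tsv(compounds: dict[str, CompoundRecord],
                           path: str | Path) -> None:
    """Fingerprints as hex-encoded bitsets, one compound per line."""
    with open(path, "w") as fh:
        fh.write("compound\tfingerprint_hex\tn_bits\n")
        for cid in sorted(compounds):
            fp = compounds[cid].fingerprint
            fh.write(f"{cid}\t{np.packbits(fp).tobytes().hex()}\t{fp.size}\n")


def read_fingerprints_tsv(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={"fingerprint_hex": str})
    out = {}
    for _, row in df.iterrows():
        bits = np.unpackbits(np.frombuffer(bytes.fromhex(row["fingerprint_hex"]),
                                           dtype=np.uint8))
        out[row["compound"]] = bits[: int(row["n_bits"])]
    return out


def write_rpairs_tsv(compounds: dict[str, CompoundRecord],
                     path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("compound_a\tcompound_b\n")
        for cid in sorted(compounds):
            for other in sorted(compounds[cid].reactant_pairs):
                if cid < other:
                    fh.write(f"{cid}\t{other}\n")


def write_counts_tsv(lit_counts: pd.DataFrame, path: str | Path) -> None:
    lit_counts.to_csv(path, sep="\t", index=False)
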