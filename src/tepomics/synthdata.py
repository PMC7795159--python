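"""Synthetic multi-omics data with planted ground truth.

Emulates the statistical structure of a two-group platelet cohort (PDAC-like
group ``A`` vs benign-like group ``B``, 11 samples each; the protein layer
keeps only 8 of the group-A samples, mirroring a proteomics subset):

* per-sample library sizes are log-normal; counts are negative binomial via
  a gamma-Poisson mixture (the edgeR model);
* a fraction of features per layer carries a planted log2 fold change
  (applied to the group-B mean, so a ``-planted_lfc`` exponent on B means
  the feature is up in the PDAC-like group);
* a module of co-expressed regulator miRNAs (correlated biological factors
  through a Gaussian copula on the gamma mixing variables) represses target
  mRNAs: each target's mean is damped by ``exp(-repression_beta * z)`` where
  ``z`` is the standardized log biological abundance of its regulator —
  inducing negative sample-wise miRNA-target correlations.  One hub
  transcript is repressed by the whole module (>= 5 regulators), the
  synthetic analogue of a highly connected, miRNA-repressed gene such as
  SPARC;
* protein spectral counts are Poisson with log-mean proportional to the
  standardized log abundance of the cognate mRNA plus independent noise —
  inducing positive mRNA-protein correlations;
* isomiR features share their parent miRNA's biological factor and fold
  change; per-group isomiR *reads* are drawn from configurable class
  mixtures (benign-like enriched for nta#G; PDAC-like for lv3p and nta#T).

Every planting is recorded in a :class:`SyntheticTruth` that is serialized
alongside the data, so downstream tests never re-derive it.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .isomir import CLASSES, MatureMiRNA, to_rna
from .normfilter import CountMatrix

logger = logging.getLogger("tepomics.synthdata")

RNA_BASES = "ACGU"

#: default per-group isomiR class mixtures.  The study describes the pattern
#: only qualitatively: benign platelets carry mostly nta#G isomiRs, PDAC
#: platelets mostly lv3p and nta#T.  These vectors encode that pattern and
#: are fully configurable.
DEFAULT_CLASS_PROBS: dict[str, dict[str, float]] = {
    "A": {  # PDAC-like
        "canonical": 0.30, "lv3p": 0.20, "nta#T": 0.15, "nta#A": 0.08,
        "lv5p": 0.07, "mlv5p": 0.05, "mlv3p": 0.04, "mv": 0.04,
        "nve": 0.03, "nta#C": 0.02, "nta#G": 0.02,
    },
    "B": {  # benign-like
        "canonical": 0.40, "nta#G": 0.25, "lv3p": 0.06, "lv5p": 0.06,
        "nta#A": 0.05, "nta#C": 0.04, "mlv5p": 0.04, "mlv3p": 0.03,
        "nta#T": 0.03, "nve": 0.02, "mv": 0.02,
    },
}


def _check_probs(probs: dict[str, float]) -> None:
    unknown = set(probs) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown isomiR classes {sorted(unknown)}")
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class probabilities sum to {total}, not 1")
    if any(p < 0 for p in probs.values()):
        raise ValueError("negative class probability")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the cohort design (11 vs 11 samples; 8 group-A samples
    in the protein layer) at desk-scale feature counts.
    """

    n_samples_per_group: int = 11
    n_protein_samples_a: int = 8
    n_mirna: int = 60
    n_mrna: int = 300
    n_intron: int = 120
    n_protein: int = 150
    lib_size_log_mean: float = math.log(1e5)
    lib_size_log_sd: float = 0.3
    nb_dispersion: float = 0.1
    frac_de: float = 0.1
    planted_lfc: float = 2.0
    repression_beta: float = 1.5
    protein_coupling: float = 0.7
    protein_noise_sd: float = 0.5
    n_regulators: int = 8
    n_solo_repressors: int = 4
    regulator_cor: float = 0.8
    isomirs_per_mirna: int = 4
    class_probs_by_group: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_CLASS_PROBS.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 2:
            raise ValueError("need >= 2 samples per group")
        if not 0 < self.n_protein_samples_a <= self.n_samples_per_group:
            raise ValueError("protein group-A subset must be within the cohort")
        for name in ("n_mirna", "n_mrna", "n_intron", "n_protein"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_intron > self.n_mrna:
            raise ValueError("intron features are a subset of mRNA features")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 0 <= self.frac_de <= 1:
            raise ValueError("frac_de must be in [0, 1]")
        if not 0 <= self.regulator_cor < 1:
            raise ValueError("regulator_cor must be in [0, 1)")
        if self.n_regulators < 5:
            raise ValueError("hub needs >= 5 regulators")
        if self.n_solo_repressors < 0:
            raise ValueError("n_solo_repressors must be non-negative")
        if self.n_regulators + self.n_solo_repressors > self.n_mirna:
            raise ValueError("more repressor miRNAs than miRNAs")
        if self.n_mrna // 2 < 1 + 2 * self.n_solo_repressors:
            raise ValueError("not enough well-expressed mRNAs for hub plus solo-repressor targets")
        for g in ("A", "B"):
            _check_probs(self.class_probs_by_group[g])


@dataclass
class SyntheticTruth:
    """Everything the generator planted, in estimable units.

    ``de_features`` maps layer -> feature -> signed log2 fold change in the
    group A over group B convention.  ``hub_transcript`` is the transcript
    repressed by the whole regulator module.
    """

    de_features: dict[str, dict[str, float]]
    target_map: dict[str, list[str]]
    protein_map: dict[str, str]
    class_mixture: dict[str, dict[str, float]]
    hub_transcript: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

def generate_reference(
    n_mirna: int,
    length_range: tuple[int, int] = (18, 24),
    flank_len: int = 10,
    seed: int = 0,
) -> list[MatureMiRNA]:
    """Random mature miRNA reference with genomic flanks.

    Sequences are uniform over {A,C,G,U}; names are unique and zero-padded;
    output is deterministic for a given seed.
    """
    lo, hi = length_range
    if not (18 <= lo <= hi <= 26):
        raise ValueError(f"length range {length_range} outside [18, 26]")
    if flank_len < 5:
        raise ValueError("flank_len must be >= 5")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out = []
    width = max(3, len(str(n_mirna)))
    for i in range(n_mirna):
        while True:
            length = int(rng.integers(lo, hi + 1))
            mature = "".join(rng.choice(list(RNA_BASES), size=length))
            if mature not in seen:
                seen.add(mature)
                break
        flank5 = "".join(rng.choice(list(RNA_BASES), size=flank_len))
        flank3 = "".join(rng.choice(list(RNA_BASES), size=flank_len))
        out.append(MatureMiRNA(f"mir-{i + 1:0{width}d}", mature, flank5, flank3))
    return out


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _lognormal_rel(rng, n: int, sd: float = 1.0) -> np.ndarray:
    raw = np.exp(rng.normal(0.0, sd, size=n))
    return raw / raw.sum()


def _gamma_mixing(rng, phi: float, shape: tuple[int, int]) -> np.ndarray:
    if phi <= 0:
        return np.ones(shape)
    return rng.gamma(1.0 / phi, phi, size=shape)


def _correlated_gamma(rng, phi: float, rho: float, shape: tuple[int, int]) -> np.ndarray:
    """Gamma(1/phi, phi) marginals with equicorrelated Gaussian copula rows."""
    if phi <= 0:
        return np.ones(shape)
    common = rng.normal(size=(1, shape[1]))
    eps = rng.normal(size=shape)
    z = math.sqrt(rho) * common + math.sqrt(1.0 - rho) * eps
    u = stats.norm.cdf(z)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return stats.gamma.ppf(u, a=1.0 / phi, scale=phi)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _draw_isomir_key(rng, parent: str, cls: str) -> str:
    """A plausible feature key (parent|class|o5|o3|tail) for a class."""
    o5 = o3 = 0
    tail = ""
    if cls.startswith("nta#"):
        base = cls[4:]
        tail = base * int(rng.integers(1, 3))
    elif cls == "lv3p":
        o3 = int(rng.choice([-2, -1, 1, 2]))
    elif cls == "lv5p":
        o5 = int(rng.choice([-2, -1, 1, 2]))
    elif cls == "mlv5p":
        o5 = int(rng.choice([-2, 2]))
        o3 = int(rng.choice([-1, 1]))
    elif cls == "mlv3p":
        o3 = int(rng.choice([-2, 2]))
        o5 = int(rng.choice([-1, 1]))
    elif cls == "mv":
        o3 = -1
        tail = "".join(rng.choice(list("ACGT"), size=2))
    # nve keys carry no offsets/tail
    return f"{parent}|{cls}|{o5}|{o3}|{tail}"


def generate_expression(
    cfg: GeneratorConfig,
    mirna_names: list[str] | None = None,
) -> tuple[dict[str, CountMatrix], SyntheticTruth]:
    """Draw all five count layers plus the ground truth.

    See the module docstring for the generative model.  Regulator miRNAs are
    planted up in group A whenever ``frac_de > 0``, so the hub transcript is
    repressed in the PDAC-like group; with ``frac_de = 0`` nothing is
    planted and the couplings act only through within-cohort biological
    variability (a pure null for differential expression).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples_per_group
    samples = [f"A{i + 1:02d}" for i in range(n)] + [f"B{i + 1:02d}" for i in range(n)]
    groups = pd.Series(["A"] * n + ["B"] * n, index=samples)
    n_s = 2 * n
    is_b = np.array([g == "B" for g in groups])

    if mirna_names is None:
        width = max(3, len(str(cfg.n_mirna)))
        mirna_names = [f"mir-{i + 1:0{width}d}" for i in range(cfg.n_mirna)]
    elif len(mirna_names) != cfg.n_mirna:
        raise ValueError("mirna_names length must equal n_mirna")
    gene_names = [f"gene-{i + 1:04d}" for i in range(cfg.n_mrna)]
    phi = cfg.nb_dispersion

    def libs() -> np.ndarray:
        return np.exp(rng.normal(cfg.lib_size_log_mean, cfg.lib_size_log_sd, size=n_s))

    de: dict[str, dict[str, float]] = {layer: {} for layer in ("mirna", "isomir", "mrna", "intron", "protein")}

    # --- miRNA layer ------------------------------------------------------
    picked = rng.choice(cfg.n_mirna, size=cfg.n_regulators + cfg.n_solo_repressors, replace=False)
    reg_idx = np.sort(picked[: cfg.n_regulators])
    solo_idx = np.sort(picked[cfg.n_regulators :])
    regulators = [mirna_names[i] for i in reg_idx]
    rel_m = _lognormal_rel(rng, cfg.n_mirna)

    n_repr = cfg.n_regulators + cfg.n_solo_repressors
    b_exp = np.zeros(cfg.n_mirna)  # exponent applied to the group-B mean
    if cfg.frac_de > 0:
        n_de = max(int(round(cfg.frac_de * cfg.n_mirna)), n_repr)
        extra = [i for i in range(cfg.n_mirna) if i not in set(picked)]
        extra_idx = rng.choice(extra, size=n_de - n_repr, replace=False) if n_de > n_repr else []
        b_exp[reg_idx] = -cfg.planted_lfc  # module regulators up in PDAC-like group
        for i in solo_idx:
            b_exp[i] = cfg.planted_lfc * rng.choice([-1.0, 1.0])
        for i in extra_idx:
            b_exp[i] = cfg.planted_lfc * rng.choice([-1.0, 1.0])
        for i in np.flatnonzero(b_exp):
            de["mirna"][mirna_names[i]] = -float(b_exp[i])  # A-vs-B convention

    mult_m = np.where(is_b[None, :], 2.0 ** b_exp[:, None], 1.0)
    g_m = _gamma_mixing(rng, phi, (cfg.n_mirna, n_s))
    if phi > 0 and cfg.regulator_cor > 0:
        g_m[reg_idx] = _correlated_gamma(rng, phi, cfg.regulator_cor, (cfg.n_regulators, n_s))
    bio_m = rel_m[:, None] * mult_m * g_m
    counts_m = rng.poisson(libs()[None, :] * bio_m)
    # coupling acts on the biological (within-cohort) variation; the
    # between-group consequence of repression is planted separately as an
    # explicit fold change on the targets, so both signals are clean
    z_m = _standardize_rows(np.log(np.maximum(g_m, 1e-300)))

    # --- target map -------------------------------------------------------
    # the co-expressed module represses the hub transcript only; separate
    # solo repressor miRNAs each damp two targets of their own, so the hub
    # is the one transcript accumulating many regulators.  Couplings are
    # planted on well-expressed transcripts (upper half of relative
    # abundance): repression of a barely-detected transcript is invisible
    # to sample-wise correlation and would make the truth unusable.
    rel_g = _lognormal_rel(rng, cfg.n_mrna)
    expressed = list(np.argsort(rel_g)[cfg.n_mrna // 2 :])
    hub_i = int(rng.choice(expressed))
    others = [i for i in expressed if i != hub_i]
    own = rng.choice(others, size=2 * len(solo_idx), replace=False) if len(solo_idx) else np.array([], dtype=int)
    target_map = {reg: [gene_names[hub_i]] for reg in regulators}
    for k, si in enumerate(solo_idx):
        target_map[mirna_names[si]] = [gene_names[own[2 * k]], gene_names[own[2 * k + 1]]]
    target_idx = {hub_i} | set(int(i) for i in own)

    # repression damping per (gene, sample)
    represt = np.ones((cfg.n_mrna, n_s))
    if cfg.repression_beta != 0:
        z_hub = z_m[reg_idx].mean(axis=0)
        z_hub = (z_hub - z_hub.mean()) / (z_hub.std() or 1.0)
        represt[hub_i] = np.exp(-cfg.repression_beta * z_hub)
        for k, si in enumerate(solo_idx):
            for gi in (int(own[2 * k]), int(own[2 * k + 1])):
                represt[gi] = np.exp(-cfg.repression_beta * z_m[si])

    # --- mRNA layer -------------------------------------------------------
    b_exp_g = np.zeros(cfg.n_mrna)
    if cfg.frac_de > 0:
        # targets carry the between-group consequence of repression: the
        # hub moves opposite to the module (down in A), each solo target
        # opposite to its repressor
        b_exp_g[hub_i] = cfg.planted_lfc
        for k, si in enumerate(solo_idx):
            for gi in (int(own[2 * k]), int(own[2 * k + 1])):
                b_exp_g[gi] = -b_exp[si]
        pool = [i for i in range(cfg.n_mrna) if i not in target_idx]
        n_de_g = min(int(round(cfg.frac_de * cfg.n_mrna)), len(pool))
        for i in rng.choice(pool, size=n_de_g, replace=False):
            b_exp_g[i] = cfg.planted_lfc * rng.choice([-1.0, 1.0])
        for i in np.flatnonzero(b_exp_g):
            de["mrna"][gene_names[i]] = -float(b_exp_g[i])
    mult_g = np.where(is_b[None, :], 2.0 ** b_exp_g[:, None], 1.0)
    g_g = _gamma_mixing(rng, phi, (cfg.n_mrna, n_s))
    bio_g = rel_g[:, None] * mult_g * represt * g_g
    counts_g = rng.poisson(libs()[None, :] * bio_g)

    # --- intron layer (subset of transcripts, same plantings) -------------
    # the hub's intron twin is kept (it must be visible in both gene
    # layers); solo targets are left out, so each solo coupling lives in a
    # single gene layer
    forced = [hub_i]
    remaining = [i for i in range(cfg.n_mrna) if i not in target_idx]
    if cfg.n_intron - 1 > len(remaining):
        raise ValueError("n_intron too large for the non-target transcript pool")
    chosen = rng.choice(remaining, size=cfg.n_intron - len(forced), replace=False)
    intron_idx = np.sort(np.concatenate([forced, chosen]).astype(int))
    intron_names = [gene_names[i] for i in intron_idx]
    rel_i = _lognormal_rel(rng, cfg.n_intron)
    mult_i = mult_g[intron_idx]
    g_i = _gamma_mixing(rng, phi, (cfg.n_intron, n_s))
    bio_i = rel_i[:, None] * mult_i * represt[intron_idx] * g_i
    counts_i = rng.poisson(libs()[None, :] * bio_i)
    for i_local, i_global in enumerate(intron_idx):
        if b_exp_g[i_global] != 0:
            de["intron"][gene_names[i_global]] = -float(b_exp_g[i_global])

    # --- protein layer ----------------------------------------------------
    prot_samples = samples[: cfg.n_protein_samples_a] + samples[n:]
    keep = np.array([s in set(prot_samples) for s in samples])
    is_b_p = is_b[keep]
    prot_names = [f"prot-{i + 1:04d}" for i in range(cfg.n_protein)]
    src_forced = sorted(target_idx)[: cfg.n_protein]
    src_pool = [i for i in range(cfg.n_mrna) if i not in set(src_forced)]
    src_rest = rng.choice(src_pool, size=cfg.n_protein - len(src_forced), replace=False)
    src_idx = np.concatenate([src_forced, src_rest]).astype(int)
    protein_map = {gene_names[src_idx[j]]: prot_names[j] for j in range(cfg.n_protein)}

    rel_p = _lognormal_rel(rng, cfg.n_protein)
    b_exp_p = np.zeros(cfg.n_protein)
    if cfg.frac_de > 0:
        n_de_p = int(round(cfg.frac_de * cfg.n_protein))
        for j in rng.choice(cfg.n_protein, size=n_de_p, replace=False):
            b_exp_p[j] = cfg.planted_lfc * rng.choice([-1.0, 1.0])
        for j in np.flatnonzero(b_exp_p):
            de["protein"][prot_names[j]] = -float(b_exp_p[j])
    mult_p = np.where(is_b_p[None, :], 2.0 ** b_exp_p[:, None], 1.0)
    z_src = _standardize_rows(np.log(np.maximum(bio_g[src_idx][:, keep], 1e-300)))
    lib_p = np.exp(rng.normal(cfg.lib_size_log_mean, cfg.lib_size_log_sd, size=keep.sum()))
    noise = rng.normal(0.0, cfg.protein_noise_sd, size=(cfg.n_protein, keep.sum()))
    lam = lib_p[None, :] * rel_p[:, None] * mult_p * np.exp(cfg.protein_coupling * z_src + noise)
    counts_p = rng.poisson(lam)

    # --- isomiR layer (features share the parent's biology) ---------------
    avg_probs = {
        c: 0.5 * (cfg.class_probs_by_group["A"].get(c, 0.0) + cfg.class_probs_by_group["B"].get(c, 0.0))
        for c in CLASSES
        if c != "canonical"
    }
    cls_names = list(avg_probs)
    cls_p = np.array([avg_probs[c] for c in cls_names])
    cls_p = cls_p / cls_p.sum()
    iso_rows, iso_names = [], []
    for mi, name in enumerate(mirna_names):
        classes = rng.choice(cls_names, size=cfg.isomirs_per_mirna, replace=False, p=cls_p)
        for cls in classes:
            key = _draw_isomir_key(rng, name, str(cls))
            w = float(np.exp(rng.normal(-1.2, 0.5)))  # isomiR fraction of parent
            iso_names.append(key)
            iso_rows.append(rel_m[mi] * w * mult_m[mi] * g_m[mi])
            if b_exp[mi] != 0:
                de["isomir"][key] = -float(b_exp[mi])
    bio_iso = np.vstack(iso_rows)
    counts_iso = rng.poisson(libs()[None, :] * bio_iso)

    matrices = {
        "mirna": CountMatrix("mirna", pd.DataFrame(counts_m, index=mirna_names, columns=samples), groups),
        "isomir": CountMatrix("isomir", pd.DataFrame(counts_iso, index=iso_names, columns=samples), groups),
        "mrna": CountMatrix("mrna", pd.DataFrame(counts_g, index=gene_names, columns=samples), groups),
        "intron": CountMatrix("intron", pd.DataFrame(counts_i, index=intron_names, columns=samples), groups),
        "protein": CountMatrix(
            "protein",
            pd.DataFrame(counts_p, index=prot_names, columns=prot_samples),
            groups.loc[prot_samples],
        ),
    }
    truth = SyntheticTruth(
        de_features=de,
        target_map=target_map,
        protein_map=protein_map,
        class_mixture={g: dict(v) for g, v in cfg.class_probs_by_group.items()},
        hub_transcript=gene_names[hub_i],
    )
    return matrices, truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

_MIN_CORE = 15


def _apply_class(rng, ref: MatureMiRNA, cls: str, max_tail: int = 3) -> str | None:
    """Build one read of the given class from a reference entry.

    Returns None when the class cannot be realized on this entry without
    colliding with the genomic template (e.g. an nta#G tail when the 3'
    flank starts with G, which would read as a templated extension).
    """
    m = ref.mature_seq
    L = len(m)
    if cls == "canonical":
        return m
    if cls == "nve":
        pos = int(rng.integers(1, L - 1))
        alt = [b for b in RNA_BASES if b != m[pos]]
        return m[:pos] + str(rng.choice(alt)) + m[pos + 1 :]
    if cls.startswith("nta#"):
        base = to_rna(cls[4:])
        if ref.flank3[0] == base:
            return None
        return m + base * int(rng.integers(1, max_tail + 1))
    if cls in ("lv5p", "lv3p"):
        d = int(rng.choice([-3, -2, -1, 1, 2, 3]))
        if cls == "lv3p":
            if d > 0:
                return m + ref.flank3[:d]
            return m[:L + d] if L + d >= _MIN_CORE else None
        if d > 0:  # 5' trim
            return m[d:] if L - d >= _MIN_CORE else None
        return ref.flank5[d:] + m
    if cls in ("mlv5p", "mlv3p"):
        big = int(rng.integers(2, 4))
        small = int(rng.integers(1, big + 1)) if cls == "mlv5p" else int(rng.integers(1, big))
        o5_mag, o3_mag = (big, small) if cls == "mlv5p" else (small, big)
        o5 = o5_mag * int(rng.choice([-1, 1]))
        o3 = o3_mag * int(rng.choice([-1, 1]))
        start = len(ref.flank5) + o5
        end = len(ref.flank5) + L + o3
        if end - start < _MIN_CORE:
            return None
        return ref.extended[start:end]
    if cls == "mv":
        # templated 3' trim by one plus a short non-templated tail
        core = m[: L - 1]
        blocked = m[L - 1]  # next templated base after the trim
        bases = [b for b in RNA_BASES if b != blocked]
        tail = str(rng.choice(bases)) + (str(rng.choice(list(RNA_BASES))) if rng.random() < 0.5 else "")
        # a 2-base uniform tail matching an nta class must stay non-templated;
        # simplest is to keep the first base fixed and accept any second base
        return core + tail
    raise ValueError(f"unknown class {cls!r}")


def generate_reads(
    reference: list[MatureMiRNA],
    class_probs_by_group: dict[str, dict[str, float]] | None = None,
    reads_per_sample: int = 10000,
    n_samples_per_group: int = 2,
    seed: int = 0,
    max_tail: int = 3,
    max_redraws: int = 50,
) -> tuple[dict[str, list[str]], dict[str, list[tuple[str, str]]], pd.Series]:
    """Per-sample synthetic small-RNA read sets with true class labels.

    Each read picks a mature miRNA uniformly at random and a class from its
    group's mixture, then applies the class's modification (templated
    trims/extensions for lv*/mlv*, a uniform non-templated tail for nta#X,
    an internal substitution for nve, trim-plus-tail for mv).  When a class
    cannot be realized on the drawn miRNA the *miRNA* is re-drawn (the class
    is kept, so empirical class fractions track the mixture); exhausting
    ``max_redraws`` re-draws falls back to a canonical read and is logged.

    Returns reads per sample, (parent, class) truth labels per read, and the
    sample -> group series.
    """
    if class_probs_by_group is None:
        class_probs_by_group = DEFAULT_CLASS_PROBS
    for g in ("A", "B"):
        _check_probs(class_probs_by_group[g])
    rng = np.random.default_rng(seed)
    reads: dict[str, list[str]] = {}
    labels: dict[str, list[tuple[str, str]]] = {}
    group_of: dict[str, str] = {}
    n_ref = len(reference)
    for g in ("A", "B"):
        probs = class_probs_by_group[g]
        cls_names = [c for c in CLASSES if probs.get(c, 0) > 0]
        cls_p = np.array([probs[c] for c in cls_names])
        cls_p = cls_p / cls_p.sum()
        for si in range(n_samples_per_group):
            sample = f"{g}{si + 1:02d}"
            group_of[sample] = g
            cls_draws = rng.choice(len(cls_names), size=reads_per_sample, p=cls_p)
            ref_draws = rng.integers(0, n_ref, size=reads_per_sample)
            r_list, l_list = [], []
            for cls_i, ref_i in zip(cls_draws, ref_draws):
                cls = cls_names[cls_i]
                ref = reference[ref_i]
                read = _apply_class(rng, ref, cls, max_tail)
                tries = 0
                while read is None and tries < max_redraws:
                    ref = reference[int(rng.integers(0, n_ref))]
                    read = _apply_class(rng, ref, cls, max_tail)
                    tries += 1
                if read is None:
                    logger.warning("class %s impossible on all drawn entries; emitting canonical", cls)
                    cls = "canonical"
                    read = ref.mature_seq
                r_list.append(read)
                l_list.append((ref.name, cls))
            reads[sample] = r_list
            labels[sample] = l_list
    return reads, labels, pd.Series(group_of)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def generate_gene_sets(
    universe: list[str],
    n_sets: int = 30,
    size_range: tuple[int, int] = (10, 40),
    seed: int = 0,
    planted: dict[str, list[str]] | None = None,
    prefix: str = "GO_SYN",
) -> dict[str, list[str]]:
    """Random gene-set collection over a universe, plus optional planted sets.

    Set names are deterministic (``GO_SYN_0001`` ...) so the same names can
    be drawn over different layer universes, which is what makes cross-layer
    term intersection meaningful on synthetic data.
    """
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    hi = min(hi, len(universe))
    lo = min(lo, hi)
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(universe, size=size, replace=False))
        sets[f"{prefix}_{i + 1:04d}"] = list(members)
    if planted:
        sets.update({k: sorted(v) for k, v in planted.items()})
    return sets
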