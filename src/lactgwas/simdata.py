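"""Synthetic dairy population generator.

Emulates the data structure of a first-lactation dairy test-day study: a
multi-generation sire-dam pedigree, biallelic SNP genotypes gene-dropped
through the pedigree, and longitudinal test-day records (DIM 5-305, roughly
monthly tests) for six traits (MY, FY, PY, FP, PP, SCS) built from
herd-test-date / age / season fixed effects plus additive-genetic and
permanent-environment random regressions on a Legendre basis.

Additive coefficient vectors a_l are sampled with covariance A (x) G (A the
numerator relationship matrix, G the user-specified coefficient covariance);
permanent-environment vectors p_l are i.i.d. with covariance P.  A record at
DIM t is

    y = HTD + Age + Season + phi(t)' a_l + phi(t)' p_l + e,   e ~ N(0, sigma_e2).

Optionally part of the additive intercept variance is planted on QTLs carried
by the gene-dropped genotypes, so association scans have known truth.

Every generator is a pure function of (config, seed); sub-seeds per stage are
drawn deterministically from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import LegendreBasis
from .genotypes import GenotypeMatrix, write_vcf
from .pedigree import UNKNOWN, Pedigree, nrm
from . import phenoqc


def _check_psd(M, name):
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(M)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError(f"{name} is not positive semi-definite")
    return M


def default_coefficient_covariance(order: int, scale: float, decay: float = 0.45,
                                   rho: float = 0.5) -> np.ndarray:
    """Smooth PSD coefficient covariance: scale * D R D with D = diag(decay^m)
    and R an AR(1)-type correlation (rho^|i-j|)."""
    m = np.arange(order + 1)
    D = np.diag(decay ** m)
    R = rho ** np.abs(np.subtract.outer(m, m))
    return scale * D @ R @ D


#: per-trait simulation settings: overall mean and the scale applied to the
#: generic (MY-sized) genetic/permanent-environment/residual structure.
TRAIT_SIM = {
    "my_kg": {"mean": 28.0, "scale": 1.0},
    "fp_pct": {"mean": 3.6, "scale": 0.10},
    "pp_pct": {"mean": 3.2, "scale": 0.045},
    "scs": {"mean": 3.0, "scale": 0.30},
}


@dataclass
class SimConfig:
    n_founders: int = 60
    n_generations: int = 2
    offspring_per_dam: int = 2
    max_sires: int | None = None  # cap on sires used per generation (AI studs)
    n_herds: int = 3
    test_day_schedule: tuple = (20, 50, 80, 110, 140, 170, 200, 230, 260, 285)
    htd_mode: str = "monthly"  # "monthly": snap tests to shared herd visit dates
    basis_order: int = 5
    G_true: np.ndarray | None = None
    P_true: np.ndarray | None = None
    sigma_e2_true: float = 8.0
    fixed_effect_spec: dict = field(
        default_factory=lambda: {"htd_sd": 2.0, "age_sd": 1.0, "season_sd": 1.0}
    )
    n_snps: int = 1000
    n_qtl: int = 5
    qtl_var_fraction: float = 0.3  # of additive intercept variance, when n_qtl > 0
    maf_range: tuple = (0.1, 0.5)
    n_chromosomes: int = 5
    chrom_length_bp: int = 100_000_000
    out_of_range_fraction: float = 0.0  # optional DIM-out-of-range records
    trait_means: dict | None = None  # overrides TRAIT_SIM means when given
    clip_traits: bool = True  # keep values inside plausible DHI edit bounds
    seed: int = 0

    def __post_init__(self):
        k = self.basis_order + 1
        if self.G_true is None:
            self.G_true = default_coefficient_covariance(self.basis_order, 6.0)
        if self.P_true is None:
            self.P_true = default_coefficient_covariance(self.basis_order, 12.0, 0.5)
        self.G_true = _check_psd(self.G_true, "G_true")
        self.P_true = _check_psd(self.P_true, "P_true")
        if self.G_true.shape[0] != k or self.P_true.shape[0] != k:
            raise ValueError("G_true/P_true dimension must equal basis_order + 1")
        if self.sigma_e2_true <= 0:
            raise ValueError("sigma_e2_true must be positive")
        sched = list(self.test_day_schedule)
        if sched != sorted(set(sched)):
            raise ValueError("test_day_schedule must be strictly increasing")
        if sched and (sched[0] < 5 or sched[-1] > 305):
            raise ValueError("test days must lie in [5, 305]")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl cannot exceed n_snps")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")

    @property
    def basis(self) -> LegendreBasis:
        return LegendreBasis(order=self.basis_order)

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the config seed."""
        import zlib

        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return np.random.default_rng(ss)


@dataclass
class SimTruth:
    """Planted truth for one (primary) trait."""

    animal_ids: np.ndarray
    cow_ids: np.ndarray  # phenotyped cows, subset of animal_ids
    a_coef: np.ndarray  # (n_animals, k) additive regression coefficients
    p_coef: np.ndarray  # (n_cows, k) permanent environment coefficients
    fixed_effects: dict = field(default_factory=dict)
    qtl_positions: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    qtl_effects: np.ndarray = field(default_factory=lambda: np.zeros((0,)))

    def genetic_value(self, basis: LegendreBasis, dim) -> np.ndarray:
        """phi(dim)' a_l for every animal."""
        return self.a_coef @ basis.row(dim)


def _sexes(n: int) -> np.ndarray:
    """Deterministic alternating sexes: even index male, odd female."""
    return np.array(["M", "F"])[np.arange(n) % 2]


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Multi-generation pedigree: founders, then each dam (female of the
    previous generation) mated to a random male of the previous generation,
    producing ``offspring_per_dam`` offspring with alternating sexes."""
    if cfg.n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = cfg.rng("pedigree")
    ids = list(range(1, cfg.n_founders + 1))
    sires = [UNKNOWN] * cfg.n_founders
    dams = [UNKNOWN] * cfg.n_founders
    byear = [2000] * cfg.n_founders
    sex = list(_sexes(cfg.n_founders))
    prev = list(zip(ids, sex))
    next_id = cfg.n_founders + 1
    for g in range(1, cfg.n_generations + 1):
        males = [i for i, s in prev if s == "M"]
        females = [i for i, s in prev if s == "F"]
        if cfg.max_sires is not None:
            males = males[: cfg.max_sires]
        if not males or not females:
            raise ValueError(
                f"impossible mating design: generation {g} has "
                f"{len(males)} males and {len(females)} females"
            )
        cur = []
        for dam in females:
            sire = males[rng.integers(len(males))]
            for j in range(cfg.offspring_per_dam):
                s = "M" if j % 2 == 0 else "F"
                ids.append(next_id)
                sires.append(sire)
                dams.append(dam)
                byear.append(2000 + g)
                sex.append(s)
                cur.append((next_id, s))
                next_id += 1
        prev = cur
    entries = pd.DataFrame(
        {"animal_id": ids, "sire_id": sires, "dam_id": dams, "birth_year": byear}
    )
    ped = Pedigree(entries)
    ped.sex = np.array(sex)  # carried for phenotyping/mating bookkeeping
    return ped


def phenotyped_cows(ped: Pedigree) -> np.ndarray:
    """Cows with records: non-founder females (first-lactation heifers)."""
    sex = getattr(ped, "sex", None)
    if sex is None:
        raise ValueError("pedigree lacks simulated sexes")
    nonfounder = (ped.entries["sire_id"] != UNKNOWN).to_numpy()
    return ped.animal_ids[nonfounder & (sex == "F")]


def simulate_genotypes(ped: Pedigree, cfg: SimConfig) -> GenotypeMatrix:
    """Gene-drop biallelic SNPs through the pedigree.

    Founder alt-allele frequencies are uniform in ``maf_range``; each parent
    transmits an alt allele with probability dosage/2 independently per locus
    (loci unlinked).
    """
    rng = cfg.rng("genotypes")
    n = len(ped)
    par = ped.parent_indices()
    freqs = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    D = np.zeros((n, cfg.n_snps))
    for i in range(n):
        s, d = par[i]
        if s < 0 and d < 0:
            D[i] = rng.binomial(2, freqs)
        else:
            if s < 0 or d < 0:
                raise ValueError("animals must have both parents known or none")
            if s >= i or d >= i:
                raise ValueError("pedigree not sorted parents-before-offspring")
            from_sire = rng.random(cfg.n_snps) < D[s] / 2.0
            from_dam = rng.random(cfg.n_snps) < D[d] / 2.0
            D[i] = from_sire.astype(float) + from_dam
    per_chrom = int(np.ceil(cfg.n_snps / cfg.n_chromosomes))
    chroms, positions = [], []
    for j in range(cfg.n_snps):
        c = j // per_chrom + 1
        within = j % per_chrom
        chroms.append(str(c))
        positions.append(int((within + 1) * cfg.chrom_length_bp / (per_chrom + 1)))
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "id": [f"snp{j + 1}" for j in range(cfg.n_snps)],
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix([int(a) for a in ped.animal_ids], variants, D)


def simulate_rr_coefficients(
    ped: Pedigree, cfg: SimConfig, genotypes: GenotypeMatrix | None = None
) -> SimTruth:
    """Sample additive and permanent-environment regression coefficients.

    Stacked additive coefficients have covariance A (x) G (animal-major);
    sampled as L_A Z L_G' with Cholesky factors of A and G.  When genotypes
    and QTLs are requested, a fraction of the additive intercept variance is
    attributed to QTL dosages and the polygenic remainder is sampled with the
    correspondingly reduced G.
    """
    rng = cfg.rng("coefficients")
    k = cfg.basis_order + 1
    G = _check_psd(cfg.G_true, "G_true")
    P = _check_psd(cfg.P_true, "P_true")
    A = nrm(ped).values
    n = len(ped)
    LA = np.linalg.cholesky(A + 1e-10 * np.eye(n))

    qtl_pos = np.array([], dtype=int)
    qtl_eff = np.zeros((0, k))
    G_poly = G.copy()
    qtl_part = np.zeros((n, k))
    if cfg.n_qtl > 0 and genotypes is not None and G[0, 0] > 0:
        qtl_pos = np.sort(
            rng.choice(cfg.n_snps, size=cfg.n_qtl, replace=False)
        )
        p = genotypes.allele_frequencies()[qtl_pos]
        var_target = cfg.qtl_var_fraction * G[0, 0]
        denom = 2.0 * p * (1.0 - p)
        beta0 = np.sqrt(var_target / cfg.n_qtl / denom)
        beta0 *= np.where(np.arange(cfg.n_qtl) % 2 == 0, 1.0, -1.0)
        qtl_eff = np.zeros((cfg.n_qtl, k))
        qtl_eff[:, 0] = beta0  # constant effect across lactation by default
        M = genotypes.dosages[:, qtl_pos]
        Mc = M - 2.0 * p
        qtl_part = Mc @ qtl_eff
        G_poly = G.copy()
        G_poly[0, 0] = G[0, 0] - var_target
        _check_psd(G_poly, "G_true minus QTL variance")

    def _sqrt(M):
        w, V = np.linalg.eigh(M)
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    LG = _sqrt(G_poly)
    a = LA @ rng.standard_normal((n, k)) @ LG.T + qtl_part
    cows = phenotyped_cows(ped)
    LP = _sqrt(P)
    p_coef = rng.standard_normal((len(cows), k)) @ LP.T
    return SimTruth(
        animal_ids=ped.animal_ids.copy(),
        cow_ids=cows,
        a_coef=a,
        p_coef=p_coef,
        qtl_positions=qtl_pos,
        qtl_effects=qtl_eff,
    )


def _nearest_mid_month(date: pd.Timestamp) -> pd.Timestamp:
    """Nearest 15th-of-month herd visit date."""
    cands = [pd.Timestamp(year=date.year, month=date.month, day=15)]
    prev = date - pd.DateOffset(months=1)
    nxt = date + pd.DateOffset(months=1)
    cands.append(pd.Timestamp(year=prev.year, month=prev.month, day=15))
    cands.append(pd.Timestamp(year=nxt.year, month=nxt.month, day=15))
    return min(cands, key=lambda c: abs((c - date).days))


def _dates_for_cows(ped: Pedigree, cows, rng):
    """Plausible birth/calving dates per cow (age at first calving 22-30 mo)."""
    byear = dict(zip(ped.animal_ids, ped.entries["birth_year"]))
    birth, calving = {}, {}
    for c in cows:
        b = pd.Timestamp(year=int(byear[c]), month=1, day=1) + pd.Timedelta(
            days=int(rng.integers(0, 330))
        )
        months = int(rng.integers(22, 31))
        calv = b + pd.DateOffset(months=months) + pd.Timedelta(days=int(rng.integers(0, 20)))
        birth[c] = b
        calving[c] = calv
    return birth, calving


def simulate_test_day_records(
    truth: SimTruth, ped: Pedigree, cfg: SimConfig
) -> pd.DataFrame:
    """Emit six-trait test-day records on the configured DIM schedule.

    MY, FP, PP and SCS are primary traits: MY uses ``truth``; FP, PP and SCS
    use independent scaled coefficient draws (same covariance shape) from
    deterministic sub-seeds.  FY and PY are derived by the product formulas
    FY = FP*MY/100 and PY = PP*MY/100 plus a small measurement noise, so the
    derivation step downstream is exercised nontrivially.
    """
    sched = list(cfg.test_day_schedule)
    if any(d < 5 or d > 305 for d in sched):
        raise ValueError("test days must lie in [5, 305]")
    basis = cfg.basis
    rng = cfg.rng("records")
    cows = truth.cow_ids
    n_cows = len(cows)
    cow_pos = {c: i for i, c in enumerate(truth.animal_ids)}

    birth, calving = _dates_for_cows(ped, cows, rng)
    herds = rng.integers(1, cfg.n_herds + 1, size=n_cows)

    rows = []
    for ci, c in enumerate(cows):
        seen = set()
        for d in sched:
            date = calving[c] + pd.Timedelta(days=int(d))
            if cfg.htd_mode == "monthly":
                # shared herd visit on the 15th of each month
                date = _nearest_mid_month(date)
                d = (date - calving[c]).days
                if d < 5 or d > 305 or date in seen:
                    continue
                seen.add(date)
            rows.append(
                {
                    "cow_id": int(c),
                    "herd": f"H{herds[ci]}",
                    "test_date": date.strftime("%Y-%m-%d"),
                    "calving_date": calving[c].strftime("%Y-%m-%d"),
                    "birth_date": birth[c].strftime("%Y-%m-%d"),
                    "dim": int(d),
                }
            )
    df = pd.DataFrame(rows)
    df = phenoqc.assign_factor_levels(df)

    spec = cfg.fixed_effect_spec
    factor_sd = {"htd": spec.get("htd_sd", 0.0), "age_class": spec.get("age_sd", 0.0),
                 "season_class": spec.get("season_sd", 0.0)}
    fixed_effects = {}
    fx = np.zeros(len(df))
    for col, sd in factor_sd.items():
        levels = df[col].unique()
        eff = dict(zip(levels, rng.normal(0.0, sd, size=len(levels)) if sd > 0 else np.zeros(len(levels))))
        fixed_effects[col] = eff
        fx += df[col].map(eff).to_numpy()
    truth.fixed_effects = fixed_effects

    Phi = basis.row(df["dim"].to_numpy())  # (N, k)
    cow_idx = df["cow_id"].map({int(c): i for i, c in enumerate(cows)}).to_numpy()
    ani_idx = df["cow_id"].map({int(a): cow_pos[a] for a in cow_pos}).to_numpy()

    def signal(a_coef, p_coef):
        return (
            np.einsum("nk,nk->n", Phi, a_coef[ani_idx])
            + np.einsum("nk,nk->n", Phi, p_coef[cow_idx])
        )

    sig_e = np.sqrt(cfg.sigma_e2_true)
    means = {t: TRAIT_SIM[t]["mean"] for t in TRAIT_SIM}
    if cfg.trait_means is not None:
        means.update(cfg.trait_means)
    my_sig = signal(truth.a_coef, truth.p_coef)
    vals = {}
    vals["my_kg"] = means["my_kg"] + fx + my_sig + rng.normal(0, sig_e, len(df))
    # secondary primary traits: independent scaled draws, same covariance shape
    for trait in ("fp_pct", "pp_pct", "scs"):
        sc = TRAIT_SIM[trait]["scale"]
        sub = cfg.rng(f"records:{trait}")
        a2 = _scaled_coefficients(ped, cfg, sub, sc)
        p2 = _scaled_pe(cfg, sub, sc, n_cows)
        vals[trait] = (
            means[trait]
            + sc * fx
            + signal(a2, p2)
            + sub.normal(0, sc * sig_e, len(df))
        )
    if cfg.clip_traits:
        vals["fp_pct"] = np.clip(vals["fp_pct"], 0.55, 8.45)
        vals["pp_pct"] = np.clip(vals["pp_pct"], 0.55, 7.45)
        vals["my_kg"] = np.clip(vals["my_kg"], 1.05, 64.9)
        vals["scs"] = np.clip(vals["scs"], 0.1, 7.9)
    df["my_kg"] = vals["my_kg"]
    df["fp_pct"] = vals["fp_pct"]
    df["pp_pct"] = vals["pp_pct"]
    scs = vals["scs"]
    df["scc_kcells_per_ml"] = phenoqc.invert_scs(scs)
    my, fp, pp = (df[c].to_numpy() for c in ("my_kg", "fp_pct", "pp_pct"))
    df["fy_kg"] = fp * my / 100.0 + rng.normal(0, 0.01, len(df))
    df["py_kg"] = pp * my / 100.0 + rng.normal(0, 0.01, len(df))
    df["scs"] = np.nan  # derived downstream by phenoqc

    if cfg.out_of_range_fraction > 0:
        n_extra = int(cfg.out_of_range_fraction * len(df))
        extra = df.sample(n=n_extra, random_state=int(rng.integers(2**31))).copy()
        extra["dim"] = rng.integers(306, 400, size=n_extra)
        df = pd.concat([df, extra], ignore_index=True)
    return df


def _scaled_coefficients(ped, cfg, rng, scale):
    A = getattr(ped, "_nrm_cache", None)
    if A is None:
        A = nrm(ped).values
        ped._nrm_cache = A
    n = len(ped)
    LA = getattr(ped, "_chol_cache", None)
    if LA is None:
        LA = np.linalg.cholesky(A + 1e-10 * np.eye(n))
        ped._chol_cache = LA
    w, V = np.linalg.eigh(cfg.G_true)
    LG = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    return scale * (LA @ rng.standard_normal((n, cfg.basis_order + 1)) @ LG.T)


def _scaled_pe(cfg, rng, scale, n_cows):
    w, V = np.linalg.eigh(cfg.P_true)
    LP = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    return scale * (rng.standard_normal((n_cows, cfg.basis_order + 1)) @ LP.T)


def simulate_dataset(cfg: SimConfig):
    """Full pipeline fixture: (records, pedigree, genotypes, truth)."""
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    truth = simulate_rr_coefficients(ped, cfg, geno)
    records = simulate_test_day_records(truth, ped, cfg)
    return records, ped, geno, truth


PHENO_COLUMNS = [
    "cow_id", "herd", "test_date", "calving_date", "birth_date", "dim",
    "my_kg", "fp_pct", "pp_pct", "scc_kcells_per_ml", "fy_kg", "py_kg", "scs",
]


def write_dataset(records: pd.DataFrame, ped: Pedigree, genotypes: GenotypeMatrix,
                  truth: SimTruth | None, outdir) -> dict:
    """Write phenotype CSV, pedigree CSV, VCF v4.2 and truth TSV; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": outdir / "phenotypes.csv",
        "pedigree": outdir / "pedigree.csv",
        "genotypes": outdir / "genotypes.vcf",
        "truth": outdir / "truth.tsv",
    }
    records[PHENO_COLUMNS].to_csv(paths["phenotypes"], index=False)
    ped.to_csv(paths["pedigree"])
    write_vcf(genotypes, paths["genotypes"])
    if truth is not None:
        k = truth.a_coef.shape[1]
        cow_pos = {c: i for i, c in enumerate(truth.animal_ids)}
        tdf = pd.DataFrame({"cow_id": truth.cow_ids})
        for m in range(k):
            tdf[f"a{m}"] = [truth.a_coef[cow_pos[c], m] for c in truth.cow_ids]
            tdf[f"p{m}"] = truth.p_coef[:, m]
        tdf.to_csv(paths["truth"], sep="\t", index=False)
        qtl = pd.DataFrame(
            {"snp_index": truth.qtl_positions,
             **{f"beta{m}": truth.qtl_effects[:, m] for m in range(truth.qtl_effects.shape[1])}}
        )
        paths["qtl"] = outdir / "qtl_truth.tsv"
        qtl.to_csv(paths["qtl"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(
        path, dtype={"herd": str, "test_date": str, "calving_date": str, "birth_date": str}
    )
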