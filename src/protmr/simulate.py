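"""Synthetic summary statistics, regions, mediation chains and expression
matrices with recorded ground truth.

The generators emulate the statistical structure of the real inputs the
pipeline is designed for — plasma cis-pQTL summary statistics (tens of
thousands of participants), a binary lung-cancer GWAS on the log-odds
scale, AR(1)-correlated regional z-scores, shared versus distinct causal
variants, protein -> risk-factor -> disease mediation chains and two-group
log2 expression matrices — without any individual-level sampling: observed
z-scores are drawn from a multivariate normal whose mean is the LD-
propagated causal signal, and betas/SEs are back-derived so that
z = beta/se holds exactly.

Every generator is bit-reproducible given (parameters, seed). One global
seed expands to per-component child seeds through
``numpy.random.SeedSequence(seed, spawn_key=...)``, so any stage can be
re-generated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import InstrumentSet, RegionSpec, SumStatsTable, make_table

__all__ = ["SimTruth", "sim_region", "sim_two_trait_region", "sim_mr_study",
           "sim_mediation_chain", "sim_expression", "sim_discovery_study",
           "StudyData"]

# Study conditions: cohort sizes of the emulated data sources
N_PQTL = 54_219          # plasma proteomics cohort
N_CASES = 7_426          # lung squamous carcinoma cases
N_CONTROLS = 55_627
N_GWAS = N_CASES + N_CONTROLS
CASE_FRACTION = N_CASES / N_GWAS


@dataclass
class SimTruth:
    """Ground truth serialized beside every simulated dataset."""

    seed: int
    params: dict = field(default_factory=dict)
    causal_effects: dict = field(default_factory=dict)
    regions: dict = field(default_factory=dict)
    mediation: dict = field(default_factory=dict)
    de_genes: dict = field(default_factory=dict)

    def to_json(self) -> str:
        import json

        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        return json.dumps(self.__dict__, default=default, indent=1)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _se_from_n(maf: np.ndarray, n: float,
               case_fraction: float | None = None) -> np.ndarray:
    """Per-allele SE of a standardized-trait (or log-odds) association:
    se = 1/sqrt(n_eff * 2*maf*(1-maf)), with n_eff = n*phi*(1-phi) for a
    binary trait with case fraction phi."""
    n_eff = n if case_fraction is None else n * case_fraction * (1 - case_fraction)
    return 1.0 / np.sqrt(n_eff * 2.0 * maf * (1.0 - maf))


def _region_table(z, se, maf, n, trait_id, trait_type, chrom, start,
                  spacing, snp_prefix):
    m = len(z)
    beta = z * se
    pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    df = pd.DataFrame({
        "snp_id": [f"{snp_prefix}_{i:04d}" for i in range(m)],
        "chrom": str(chrom),
        "pos": start + spacing * np.arange(m),
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": maf,
        "beta": beta,
        "se": se,
        "pval": pval,
        "n": float(n),
    })
    return make_table(df, trait_id, trait_type)


def _ar1(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def sim_region(m_snps: int, ld_rho: float, causal_idx, beta_causal,
               n: float, maf_range=(0.05, 0.5), seed: int = 0,
               trait_id: str = "trait", trait_type: str = "quantitative",
               case_fraction: float | None = None, chrom="1",
               start: int = 1_000_000, spacing: int = 5_000,
               snp_prefix: str | None = None, rng=None):
    """One cis region on an AR(1) LD grid.

    The causal SNP's z-score is beta_causal/se; the expected z-vector is
    the LD matrix times that causal z, and the observed z is one draw from
    MVN(expected, R). Returns (SumStatsTable, r² DataFrame, SimTruth).
    """
    if m_snps < 1 or not abs(ld_rho) < 1:
        raise ValueError("need m_snps >= 1 and |ld_rho| < 1")
    rng = rng or _rng(seed, 0)
    maf = rng.uniform(*maf_range, size=m_snps)
    se = _se_from_n(maf, n, case_fraction)
    z_causal = np.zeros(m_snps)
    if causal_idx is not None:
        idx = np.atleast_1d(causal_idx)
        bc = np.broadcast_to(np.atleast_1d(beta_causal), idx.shape)
        z_causal[idx] = bc / se[idx]
    r = _ar1(m_snps, ld_rho)
    mean = r @ z_causal
    chol = np.linalg.cholesky(r + 1e-12 * np.eye(m_snps))
    z = mean + chol @ rng.standard_normal(m_snps)
    prefix = snp_prefix or f"rs{trait_id}"
    table = _region_table(z, se, maf, n, trait_id, trait_type, chrom, start,
                          spacing, prefix)
    ld = pd.DataFrame(r ** 2, index=table.snps, columns=table.snps)
    truth = SimTruth(seed, params={"m_snps": m_snps, "ld_rho": ld_rho},
                     causal_effects={trait_id: beta_causal},
                     regions={trait_id: {"causal_idx": causal_idx,
                                         "expected_z": mean}})
    return table, ld, truth


def sim_two_trait_region(shared: bool | str, m_snps: int = 100,
                         ld_rho: float = 0.9, z1: float = 8.0,
                         z2: float = 8.0, n1: float = N_PQTL,
                         n2: float = N_GWAS,
                         case_fraction2: float = CASE_FRACTION,
                         min_separation: int = 40, maf_range=(0.05, 0.5),
                         seed: int = 0):
    """Paired regional tables for colocalization.

    ``shared`` may be True/"shared" (one causal variant drives both
    traits), False/"distinct" (two causal variants at least
    ``min_separation`` SNPs apart, so their r² is negligible on the AR(1)
    grid), or "null" (no causal variant for either trait). Both studies see
    the same LD; their noise draws are independent.
    """
    mode = {True: "shared", False: "distinct"}.get(shared, shared)
    rng = _rng(seed, 1)
    maf = rng.uniform(*maf_range, size=m_snps)
    se1 = _se_from_n(maf, n1)
    se2 = _se_from_n(maf, n2, case_fraction2)
    r = _ar1(m_snps, ld_rho)
    chol = np.linalg.cholesky(r + 1e-12 * np.eye(m_snps))

    if mode == "null":
        i1 = i2 = None
    else:
        i1 = int(rng.integers(0, m_snps))
        if mode == "shared":
            i2 = i1
        else:
            i2 = (i1 + int(rng.integers(min_separation,
                                        m_snps - min_separation))) % m_snps

    def draw(zc_idx, z_target, se):
        zc = np.zeros(m_snps)
        if zc_idx is not None:
            zc[zc_idx] = z_target
        mean = r @ zc
        return mean + chol @ rng.standard_normal(m_snps)

    zz1 = draw(i1, z1, se1)
    zz2 = draw(i2, z2, se2)
    t1 = _region_table(zz1, se1, maf, n1, "protein", "quantitative",
                       "1", 1_000_000, 5_000, "rsREG")
    t2 = _region_table(zz2, se2, maf, n2, "outcome", "binary",
                       "1", 1_000_000, 5_000, "rsREG")
    ld = pd.DataFrame(r ** 2, index=t1.snps, columns=t1.snps)
    truth = SimTruth(seed, params={"mode": mode, "m_snps": m_snps,
                                   "ld_rho": ld_rho, "z1": z1, "z2": z2},
                     regions={"causal_idx_1": i1, "causal_idx_2": i2})
    return t1, t2, ld, truth


def sim_mr_study(n_proteins: int, n_effects: int,
                 instruments_per_protein: int,
                 effect_size: float = float(np.log(0.35)),
                 pleiotropy: str = "none", pleiotropy_scale: float = 0.1,
                 n_exp: float = N_PQTL, n_out: float = N_GWAS,
                 case_fraction: float = CASE_FRACTION,
                 beta_exp_range=(0.1, 0.3), maf_range=(0.1, 0.5),
                 seed: int = 0):
    """A proteome screen with known truth: independent strong instruments
    per protein, the first ``n_effects`` proteins carrying the true
    log-odds effect ``effect_size``, the rest null.

    ``pleiotropy``: "none", "balanced" (zero-mean N(0, scale) direct
    effects on the outcome) or "directional" (constant ``scale`` added to
    every outcome beta). Exposure and outcome noise draws are independent
    (two-sample design). Returns ({protein: InstrumentSet}, outcome
    SumStatsTable, SimTruth).
    """
    rng = _rng(seed, 2)
    m = instruments_per_protein
    exposures: dict = {}
    out_frames = []
    truth_eff: dict = {}
    chroms = [c for c in range(1, 23) if c != 6]
    for p in range(n_proteins):
        pid = f"P{p:03d}"
        theta = effect_size if p < n_effects else 0.0
        truth_eff[pid] = theta
        maf = rng.uniform(*maf_range, size=m)
        se_e = _se_from_n(maf, n_exp)
        se_o = _se_from_n(maf, n_out, case_fraction)
        # directional pleiotropy is defined in the orientation beta_exp > 0
        # (a constant direct effect on signed instruments would cancel once
        # estimators orient them), so that mode keeps effects positive
        signs = (np.ones(m) if pleiotropy == "directional"
                 else rng.choice([-1.0, 1.0], size=m))
        b = rng.uniform(*beta_exp_range, size=m) * signs
        be_hat = b + se_e * rng.standard_normal(m)
        if pleiotropy == "balanced":
            alpha = pleiotropy_scale * rng.standard_normal(m)
        elif pleiotropy == "directional":
            alpha = np.full(m, pleiotropy_scale)
        else:
            alpha = np.zeros(m)
        bo_hat = theta * b + alpha + se_o * rng.standard_normal(m)

        chrom = str(chroms[p % len(chroms)])
        start = 10_000_000 + 5_000_000 * (p // len(chroms))
        df = pd.DataFrame({
            "snp_id": [f"rs{pid}_{j:03d}" for j in range(m)],
            "chrom": chrom,
            "pos": start + 50_000 * np.arange(m),
            "effect_allele": "A", "other_allele": "G",
            "eaf": maf, "beta": be_hat, "se": se_e,
            "pval": np.clip(2 * stats.norm.sf(np.abs(be_hat / se_e)),
                            np.finfo(float).tiny, 1.0),
            "n": float(n_exp),
        })
        exposures[pid] = InstrumentSet(pid, make_table(df, pid), [], "ok")
        out = df.copy()
        out["beta"] = bo_hat
        out["se"] = se_o
        out["pval"] = np.clip(2 * stats.norm.sf(np.abs(bo_hat / se_o)),
                              np.finfo(float).tiny, 1.0)
        out["n"] = float(n_out)
        out_frames.append(out)
    outcome = make_table(pd.concat(out_frames, ignore_index=True),
                         "outcome", "binary")
    truth = SimTruth(seed, params={"n_proteins": n_proteins,
                                   "n_effects": n_effects,
                                   "instruments_per_protein": m,
                                   "pleiotropy": pleiotropy,
                                   "pleiotropy_scale": pleiotropy_scale},
                     causal_effects=truth_eff)
    return exposures, outcome, truth


def sim_mediation_chain(beta1: float, beta2: float, direct: float,
                        n_instruments_protein: int = 10,
                        n_instruments_factor: int = 10,
                        n_protein: float = N_PQTL,
                        n_factor: float = 200_000, n_out: float = N_GWAS,
                        case_fraction: float = CASE_FRACTION,
                        seed: int = 0):
    """Three linked summary-statistics tables realizing the chain
    protein -> factor -> outcome with total = direct + beta1*beta2 by
    construction.

    Protein instruments live on chr1 (cis cluster), factor instruments on
    chr2; each table reports both SNP sets so the full selection +
    harmonization machinery can run. Returns (protein_table, factor_table,
    outcome_table, SimTruth); the truth records the cis windows to use for
    instrument selection on each side.
    """
    rng = _rng(seed, 3)
    total = direct + beta1 * beta2
    mp, mf = n_instruments_protein, n_instruments_factor

    maf_p = rng.uniform(0.1, 0.5, size=mp)
    maf_f = rng.uniform(0.1, 0.5, size=mf)
    maf = np.concatenate([maf_p, maf_f])
    b = rng.uniform(0.1, 0.3, size=mp) * rng.choice([-1, 1], size=mp)
    g = rng.uniform(0.03, 0.06, size=mf) * rng.choice([-1, 1], size=mf)

    se_prot = _se_from_n(maf, n_protein)
    se_fact = _se_from_n(maf, n_factor)
    se_out = _se_from_n(maf, n_out, case_fraction)

    mean_prot = np.concatenate([b, np.zeros(mf)])
    mean_fact = np.concatenate([beta1 * b, g])
    mean_out = np.concatenate([total * b, beta2 * g])

    ids = [f"rsPCHAIN_{j:03d}" for j in range(mp)] + \
          [f"rsFCHAIN_{j:03d}" for j in range(mf)]
    chrom = ["1"] * mp + ["2"] * mf
    pos = np.concatenate([1_000_000 + 50_000 * np.arange(mp),
                          30_000_000 + 50_000 * np.arange(mf)])

    def table(mean, se, n, tid, ttype):
        beta = mean + se * rng.standard_normal(len(mean))
        df = pd.DataFrame({
            "snp_id": ids, "chrom": chrom, "pos": pos,
            "effect_allele": "A", "other_allele": "G",
            "eaf": maf, "beta": beta, "se": se,
            "pval": np.clip(2 * stats.norm.sf(np.abs(beta / se)),
                            np.finfo(float).tiny, 1.0),
            "n": float(n),
        })
        return make_table(df, tid, ttype)

    protein_t = table(mean_prot, se_prot, n_protein, "protein",
                      "quantitative")
    factor_t = table(mean_fact, se_fact, n_factor, "factor", "quantitative")
    outcome_t = table(mean_out, se_out, n_out, "outcome", "binary")
    truth = SimTruth(
        seed,
        params={"beta1": beta1, "beta2": beta2, "direct": direct},
        mediation={"total": total, "indirect": beta1 * beta2,
                   "proportion": (beta1 * beta2) / total if total else None,
                   "protein_cis": ("1", 1, 20_000_000),
                   "factor_cis": ("2", 20_000_001, 60_000_000)})
    return protein_t, factor_t, outcome_t, truth


def sim_expression(n_genes: int, n_de: int, log2fc: float,
                   n_per_group: int, sigma: float = 0.5, seed: int = 0,
                   d0: float = 4.0, gene_names=None):
    """Two-group log2 expression matrix with planted fold changes.

    The first ``n_de`` genes get a tumor-minus-normal shift of ``log2fc``
    (a scalar is used as-is, an array gives per-gene shifts). Per-gene
    noise SDs are drawn from a scaled inverse-chi-square around ``sigma``
    (d0 prior df), the regime variance moderation targets.
    ``n_per_group`` may be an int or a (tumor, normal) pair. Returns
    (DataFrame genes × samples, labels list, SimTruth).
    """
    n1, n2 = (n_per_group if isinstance(n_per_group, (tuple, list))
              else (n_per_group, n_per_group))
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    rng = _rng(seed, 4)
    shifts = np.zeros(n_genes)
    if n_de:
        fc = np.broadcast_to(np.atleast_1d(log2fc), (n_de,))
        shifts[:n_de] = fc
    sig2 = sigma ** 2 * d0 / rng.chisquare(d0, size=n_genes)
    sig = np.sqrt(sig2)
    base = rng.normal(6.0, 1.0, size=n_genes)
    tumor = base[:, None] + shifts[:, None] + \
        sig[:, None] * rng.standard_normal((n_genes, n1))
    normal = base[:, None] + sig[:, None] * rng.standard_normal((n_genes, n2))
    if gene_names is None:
        gene_names = [f"G{i:04d}" for i in range(n_genes)]
    cols = [f"T{i}" for i in range(n1)] + [f"N{i}" for i in range(n2)]
    mat = pd.DataFrame(np.hstack([tumor, normal]), index=gene_names,
                       columns=cols)
    labels = ["tumor"] * n1 + ["normal"] * n2
    truth = SimTruth(seed, params={"n_genes": n_genes, "n_de": n_de,
                                   "log2fc": log2fc, "sigma": sigma},
                     de_genes={g: float(s) for g, s in
                               zip(gene_names[:n_de], shifts[:n_de])})
    return mat, labels, truth


@dataclass
class StudyData:
    """Everything one end-to-end discovery run consumes, plus its truth."""

    pqtl_tables: dict            # protein -> cis SumStatsTable (+ trans nulls)
    pqtl_ld: dict                # protein -> r2 DataFrame over cis SNPs
    outcome: SumStatsTable       # disease GWAS: all cis regions + own loci
    outcome_ld: pd.DataFrame     # r2 over the disease loci
    anchors: dict                # protein -> (chrom, tss)
    expression: dict             # dataset -> (matrix, labels)
    ppi_edges: pd.DataFrame
    drug_targets: list
    druggable: dict              # protein -> bool
    factor_tables: dict          # factor -> SumStatsTable
    factor_regions: dict         # factor -> RegionSpec of its own loci
    factor_ld: dict              # factor -> r2 DataFrame
    truth: SimTruth

    @property
    def proteins(self) -> list:
        return list(self.pqtl_tables)


def sim_discovery_study(n_proteins: int = 30, n_causal: int = 5,
                        snps_per_region: int = 60, ld_rho: float = 0.9,
                        pqtl_z: float = 35.0, seed: int = 0,
                        effect_sizes=None,
                        mediation_proportion: float = 0.6946) -> StudyData:
    """A complete synthetic discovery study with known truth.

    ``n_causal`` proteins carry true log-odds effects (default magnitudes
    around |log OR| of 0.35–2.0, alternating protective/risk); each protein
    has one causal cis-pQTL at |z| ~ ``pqtl_z`` inside a 60-SNP AR(1)
    region — sentinel strength chosen so the weakest planted effect is
    detected with >99% power at the emulated cohort sizes — and causal proteins share that variant with the outcome GWAS.
    One risk protein is given a mediation chain through a smoking-like
    factor planted at ``mediation_proportion`` of its total effect.
    Expression, PPI, druggability and disease-locus (reverse-MR) inputs are
    generated to exercise every downstream stage.
    """
    if effect_sizes is None:
        effect_sizes = [np.log(0.35), np.log(2.0), np.log(0.5),
                        np.log(1.8), np.log(0.45)]
    thetas = [float(effect_sizes[i % len(effect_sizes)])
              for i in range(n_causal)]
    rng = _rng(seed, 5)
    chroms = [str(c) for c in range(1, 23) if c != 6]

    pids = [f"PROT{p:02d}" for p in range(n_proteins)]
    causal = {pid: thetas[i] for i, pid in enumerate(pids[:n_causal])}
    mediated_pid = pids[1] if n_causal >= 2 else pids[0]

    pqtl_tables: dict = {}
    pqtl_ld: dict = {}
    anchors: dict = {}
    out_frames = []
    region_truth: dict = {}

    # factor chain coefficients: indirect/total = mediation_proportion
    theta_med = causal.get(mediated_pid, 0.0)
    beta1 = 0.6
    beta2 = (mediation_proportion * theta_med / beta1) if theta_med else 0.0

    factor_ids = ["F_SMOKING", "F_ALCOHOL", "F_BMI", "F_ACTIVITY"]
    n_factor = 200_000.0
    factor_rows: dict = {fid: [] for fid in factor_ids}

    m = snps_per_region
    r = _ar1(m, ld_rho)
    chol = np.linalg.cholesky(r + 1e-12 * np.eye(m))

    for p, pid in enumerate(pids):
        chrom = chroms[p % len(chroms)]
        start = 1_000_000 + 5_000_000 * (p // len(chroms))
        theta = causal.get(pid, 0.0)
        maf = rng.uniform(0.05, 0.5, size=m)
        se_e = _se_from_n(maf, N_PQTL)
        se_o = _se_from_n(maf, N_GWAS, CASE_FRACTION)
        ci = int(rng.integers(m // 4, 3 * m // 4))
        sign = float(rng.choice([-1.0, 1.0]))
        beta_pqtl = sign * pqtl_z * se_e[ci]

        zc_e = np.zeros(m)
        zc_e[ci] = beta_pqtl / se_e[ci]
        z_e = r @ zc_e + chol @ rng.standard_normal(m)

        zc_o = np.zeros(m)
        zc_o[ci] = theta * beta_pqtl / se_o[ci]
        z_o = r @ zc_o + chol @ rng.standard_normal(m)

        exp_t = _region_table(z_e, se_e, maf, N_PQTL, pid, "quantitative",
                              chrom, start, 5_000, f"rs{pid}")
        out_t = _region_table(z_o, se_o, maf, N_GWAS, "outcome", "binary",
                              chrom, start, 5_000, f"rs{pid}")
        pqtl_ld[pid] = pd.DataFrame(r ** 2, index=exp_t.snps,
                                    columns=exp_t.snps)
        anchors[pid] = (chrom, start + 5_000 * (m // 2))
        pqtl_tables[pid] = exp_t
        out_frames.append(out_t.df)
        region_truth[pid] = {"causal_idx": ci, "beta_pqtl": beta_pqtl,
                             "theta": theta, "chrom": chrom}

        # factor GWAS view of this protein's cis SNPs: only the mediated
        # protein propagates beta1 * pQTL effect into the smoking factor
        se_f = _se_from_n(maf, n_factor)
        for fid in factor_ids:
            b1 = beta1 if (fid == "F_SMOKING" and pid == mediated_pid) else 0.0
            zc_f = np.zeros(m)
            zc_f[ci] = b1 * beta_pqtl / se_f[ci]
            z_f = r @ zc_f + chol @ rng.standard_normal(m)
            ft = _region_table(z_f, se_f, maf, n_factor, fid,
                               "quantitative", chrom, start, 5_000,
                               f"rs{pid}")
            factor_rows[fid].append(ft.df)

    # disease-specific loci: strong in the outcome, null for every protein
    n_loci = 8
    maf_d = rng.uniform(0.1, 0.5, size=n_loci)
    se_do = _se_from_n(maf_d, N_GWAS, CASE_FRACTION)
    z_do = rng.choice([-1, 1], size=n_loci) * rng.uniform(10, 14, size=n_loci)
    disease_ids = [f"rsDISEASE_{j:02d}" for j in range(n_loci)]
    disease_df = pd.DataFrame({
        "snp_id": disease_ids, "chrom": "20",
        "pos": 40_000_000 + 1_000_000 * np.arange(n_loci),
        "effect_allele": "A", "other_allele": "G", "eaf": maf_d,
        "beta": z_do * se_do, "se": se_do,
        "pval": np.clip(2 * stats.norm.sf(np.abs(z_do)),
                        np.finfo(float).tiny, 1.0),
        "n": float(N_GWAS)})
    out_frames.append(disease_df)
    outcome = make_table(pd.concat(out_frames, ignore_index=True),
                         "outcome", "binary")
    outcome_ld = pd.DataFrame(np.eye(n_loci), index=disease_ids,
                              columns=disease_ids)

    # the same loci appear in every pQTL table with null protein effects
    se_dp = _se_from_n(maf_d, N_PQTL)
    for pid in pids:
        z_null = rng.standard_normal(n_loci)
        null_df = disease_df.copy()
        null_df["beta"] = z_null * se_dp
        null_df["se"] = se_dp
        null_df["pval"] = np.clip(2 * stats.norm.sf(np.abs(z_null)),
                                  np.finfo(float).tiny, 1.0)
        null_df["n"] = float(N_PQTL)
        pqtl_tables[pid] = SumStatsTable(
            pid, "quantitative",
            pd.concat([pqtl_tables[pid].df, null_df], ignore_index=True))

    # factor-specific loci on chr15 (step-2 instruments) and their outcome
    # effects beta2 * gamma for the mediating factor only
    factor_tables: dict = {}
    factor_regions: dict = {}
    factor_ld: dict = {}
    mf = 10
    extra_out = []
    for k, fid in enumerate(factor_ids):
        maf_f = rng.uniform(0.1, 0.5, size=mf)
        se_ff = _se_from_n(maf_f, n_factor)
        g = rng.uniform(0.03, 0.06, size=mf) * rng.choice([-1, 1], size=mf)
        g_hat = g + se_ff * rng.standard_normal(mf)
        fids_snp = [f"rs{fid}_{j:02d}" for j in range(mf)]
        start_f = 20_000_000 + 3_000_000 * k
        fdf = pd.DataFrame({
            "snp_id": fids_snp, "chrom": "15",
            "pos": start_f + 50_000 * np.arange(mf),
            "effect_allele": "A", "other_allele": "G", "eaf": maf_f,
            "beta": g_hat, "se": se_ff,
            "pval": np.clip(2 * stats.norm.sf(np.abs(g_hat / se_ff)),
                            np.finfo(float).tiny, 1.0),
            "n": n_factor})
        factor_rows[fid].append(fdf)
        factor_tables[fid] = make_table(
            pd.concat(factor_rows[fid], ignore_index=True), fid)
        factor_regions[fid] = RegionSpec("15", start_f,
                                         start_f + 50_000 * mf)
        factor_ld[fid] = pd.DataFrame(np.eye(mf), index=fids_snp,
                                      columns=fids_snp)
        b2 = beta2 if fid == "F_SMOKING" else 0.0
        se_og = _se_from_n(maf_f, N_GWAS, CASE_FRACTION)
        bo = b2 * g + se_og * rng.standard_normal(mf)
        odf = fdf.copy()
        odf["beta"] = bo
        odf["se"] = se_og
        odf["pval"] = np.clip(2 * stats.norm.sf(np.abs(bo / se_og)),
                              np.finfo(float).tiny, 1.0)
        odf["n"] = float(N_GWAS)
        extra_out.append(odf)
    outcome = make_table(pd.concat([outcome.df] + extra_out,
                                   ignore_index=True), "outcome", "binary")

    # expression: planted fold changes match the MR direction (protective
    # proteins down-regulated in tumors); the last causal protein is DE in
    # the validation dataset only
    n_null_genes = 170
    genes = pids + [f"NULL{g:03d}" for g in range(n_null_genes)]
    shifts_a = np.zeros(len(genes))
    shifts_b = np.zeros(len(genes))
    de_truth: dict = {}
    for i, pid in enumerate(pids[:n_causal]):
        fc = -2.0 if causal[pid] < 0 else 2.0
        shifts_b[i] = fc
        if i < n_causal - 1:
            shifts_a[i] = fc
        de_truth[pid] = fc
    expression = {}
    for ds, shifts, sizes, sub in (("discovery", shifts_a, (61, 14), 6),
                                   ("validation", shifts_b, (502, 51), 7)):
        mat, labels, _ = sim_expression(
            len(genes), n_de=len(genes), log2fc=shifts,
            n_per_group=sizes, sigma=0.5, seed=seed + sub,
            gene_names=genes)
        expression[ds] = (mat, labels)

    drug_targets = ["EGFR", "ERBB2", "FGFR1", "PTK2"]
    edges = []
    if n_causal >= 1:
        edges.append((pids[0], "EGFR", 0.92))
    if n_causal >= 2:
        edges.append((pids[1], "ERBB2", 0.81))
    if n_causal >= 3:
        edges.append((pids[2], "EGFR", 0.45))
    if n_causal >= 4:
        edges.append((pids[3], "FGFR1", 0.30))   # below the 0.40 cutoff
    edges += [(pids[-1], pids[-2], 0.55), ("NULLX", "NULLY", 0.70)]
    ppi_edges = pd.DataFrame(edges, columns=["a", "b", "score"])
    druggable = {pid: False for pid in pids}
    for i, pid in enumerate(pids[:n_causal]):
        druggable[pid] = i in (0, 1, 3)

    truth = SimTruth(
        seed,
        params={"n_proteins": n_proteins, "n_causal": n_causal,
                "snps_per_region": snps_per_region, "ld_rho": ld_rho,
                "pqtl_z": pqtl_z},
        causal_effects={pid: causal.get(pid, 0.0) for pid in pids},
        regions=region_truth,
        mediation={"protein": mediated_pid, "factor": "F_SMOKING",
                   "beta1": beta1, "beta2": beta2,
                   "total": theta_med,
                   "proportion": mediation_proportion if theta_med else None},
        de_genes=de_truth)
    return StudyData(pqtl_tables, pqtl_ld, outcome, outcome_ld, anchors,
                     expression, ppi_edges, drug_targets, druggable,
                     factor_tables, factor_regions, factor_ld, truth)
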