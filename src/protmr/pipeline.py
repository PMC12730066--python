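"""End-to-end orchestration of the discovery run plus study-directory IO.

Stage order mirrors the analysis design: instrument selection -> proteome
MR screen with sensitivity statistics -> directionality (Steiger filtering
and bidirectional MR; proteins with reverse-causal evidence are excluded
before colocalization) -> colocalization of the surviving hits ->
differential expression -> evidence tiering -> two-step mediation ->
report. Every stage writes a TSV and logs its input/output row counts into
a JSON run manifest; the manifest is emitted even when a stage fails.

Data outputs are a pure function of (inputs, config, seed): re-running
with the same seed reproduces them byte for byte (the manifest additionally
records wall-clock times, which naturally vary).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .sumstats import (InstrumentSet, MHC_GRCH37, RegionSpec, SumStatsTable,
                       harmonize, make_table, select_instruments)
from .mr import mr_all_methods, run_proteome_mr
from .direction import reverse_mr, steiger_filter
from .coloc import ColocPriors, coloc_all_hits
from .diffexpr import concordance, de_test, mr_de_direction_check
from .evidence import (EvidenceProfile, evidence_matrix, filter_ppi_edges,
                       ppi_connectivity)
from .mediation import mediation_frame, run_two_step
from .simulate import StudyData, SimTruth

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "report",
           "write_study", "load_study"]

_STAGES = ["instruments", "screen", "direction", "coloc", "de", "evidence",
           "mediation", "report"]
_DEPS = {
    "instruments": set(),
    "screen": {"instruments"},
    "direction": {"screen"},
    "coloc": {"direction"},
    "de": set(),
    "evidence": {"coloc", "de"},
    "mediation": {"direction"},
    "report": {"evidence", "mediation"},
}


@dataclass
class RunConfig:
    """All thresholds of the run; defaults are the published values where
    one is stated (p < 5e-8 instruments, r² < 0.001 clumping, MHC excluded,
    alpha 0.05 Bonferroni family, PPH4 bands 0.75/0.60, |log2FC| > 1 and
    adjusted p < 0.05 for expression, PPI score >= 0.40)."""

    p_max: float = 5e-8
    r2_max: float = 0.001
    alpha: float = 0.05
    cis_window: int = 1_000_000       # instrument selection, around the TSS
    coloc_window: int = 500_000       # colocalization region
    pph4_strong: float = 0.75
    pph4_moderate: float = 0.60
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_sd1: float = 0.15
    coloc_sd2: float = 0.2
    de_lfc: float = 1.0
    de_alpha: float = 0.05
    ppi_min_score: float = 0.40
    palindrome_eaf_limit: float = 0.42
    reverse_alpha: float = 0.05
    mediation_alpha: float = 0.05
    methods: str = "all"
    nboot: int = 1000
    seed: int = 0

    def validate(self):
        for name in ("p_max", "alpha", "r2_max", "de_alpha",
                     "reverse_alpha", "mediation_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} outside (0,1)")
        if not 0 <= self.ppi_min_score <= 1:
            raise ValueError("ppi_min_score outside [0,1]")
        return self

    def priors(self) -> ColocPriors:
        return ColocPriors(self.coloc_p1, self.coloc_p2, self.coloc_p12,
                           self.coloc_sd1, self.coloc_sd2)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    seed: int = 0
    stages: list = field(default_factory=list)
    status: str = "ok"
    failure: str | None = None

    def record(self, name, n_in, n_out, dt):
        self.stages.append({"stage": name, "rows_in": int(n_in),
                            "rows_out": int(n_out),
                            "seconds": round(dt, 3)})

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def _expand(stages) -> list:
    want = set(stages or _STAGES)
    added = True
    while added:
        added = False
        for s in list(want):
            for d in _DEPS[s]:
                if d not in want:
                    want.add(d)
                    added = True
    return [s for s in _STAGES if s in want]


def run_pipeline(study: StudyData, config: RunConfig | None = None,
                 outdir=None, stages=None) -> RunManifest:
    """Execute the discovery pipeline on a study, writing one TSV per
    stage under ``outdir`` (created if needed) and returning the manifest.

    ``stages`` restricts which stages run; prerequisites are pulled in
    automatically.
    """
    config = (config or RunConfig()).validate()
    outdir = Path(outdir or "protmr_run")
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(dataclasses.asdict(config), seed=config.seed)
    todo = _expand(stages)
    state: dict = {}
    try:
        for stage in todo:
            t0 = time.perf_counter()
            n_in, n_out = _run_stage(stage, study, config, outdir, state)
            manifest.record(stage, n_in, n_out, time.perf_counter() - t0)
    except Exception as exc:  # stage hard error: keep prior outputs
        manifest.status = "failed"
        manifest.failure = f"{stage}: {exc}"
        manifest.write(outdir / "manifest.json")
        raise
    manifest.write(outdir / "manifest.json")
    return manifest


def _run_stage(stage, study, config, outdir, state):
    fn = globals()[f"_stage_{stage}"]
    return fn(study, config, outdir, state)


def _stage_instruments(study, config, outdir, state):
    instruments: dict = {}
    log_rows = []
    n_in = 0
    for pid, table in study.pqtl_tables.items():
        n_in += len(table)
        chrom, tss = study.anchors[pid]
        cis = RegionSpec(str(chrom), max(1, tss - config.cis_window),
                         tss + config.cis_window)
        inst = select_instruments(table, p_max=config.p_max, cis=cis,
                                  mhc=MHC_GRCH37, ld=study.pqtl_ld.get(pid),
                                  r2_max=config.r2_max)
        instruments[pid] = inst
        log_rows += [{"protein": pid, "snp_id": s, "reason": r}
                     for s, r in inst.selection_log]
    state["instruments"] = instruments
    pd.DataFrame(log_rows).to_csv(outdir / "selection_log.tsv", sep="\t",
                                  index=False)
    kept = pd.concat([i.table.df.assign(protein=p)
                      for p, i in instruments.items() if i.n_instruments],
                     ignore_index=True)
    kept.to_csv(outdir / "instruments.tsv", sep="\t", index=False)
    return n_in, len(kept)


def _stage_screen(study, config, outdir, state):
    screen = run_proteome_mr(state["instruments"], study.outcome,
                             alpha=config.alpha, methods=config.methods,
                             nboot=config.nboot, seed=config.seed,
                             palindrome_eaf_limit=config.palindrome_eaf_limit)
    state["screen"] = screen
    frame = screen.to_frame()
    frame.to_csv(outdir / "screen.tsv", sep="\t", index=False)
    return len(screen.results), len(frame)


def _stage_direction(study, config, outdir, state):
    screen = state["screen"]
    hits = screen.significant_proteins
    steiger_rows, reverse_rows, final_rows = [], [], []
    candidates = []
    for pid in hits:
        r = screen.results[pid]
        filtered, records = steiger_filter(r.harmonized)
        for rec in records:
            steiger_rows.append({"protein": pid, **dataclasses.asdict(rec)})
        rev = reverse_mr(study.outcome, study.pqtl_tables[pid],
                         p_max=config.p_max, ld=study.outcome_ld,
                         r2_max=config.r2_max, alpha=config.reverse_alpha)
        reverse_rows.append({
            "protein": pid, "status": rev.status,
            "reverse_beta": rev.estimate.beta if rev.estimate else np.nan,
            "reverse_pval": rev.estimate.pval if rev.estimate else np.nan,
            "reverse_causal": rev.reverse_causal})
        excluded = (rev.reverse_causal is True) or filtered.nsnp == 0
        if filtered.nsnp:
            primary, _, _ = mr_all_methods(filtered, methods="primary",
                                           seed=config.seed)
        else:
            primary = None
        final_rows.append({
            "protein": pid,
            "nsnp_prefilter": r.harmonized.nsnp,
            "nsnp_postfilter": filtered.nsnp,
            "beta_postfilter": primary.beta if primary else np.nan,
            "se_postfilter": primary.se if primary else np.nan,
            "pval_postfilter": primary.pval if primary else np.nan,
            "or_postfilter": primary.or_ if primary else np.nan,
            "excluded": excluded,
            "exclusion_reason": (
                "reverse-causal" if rev.reverse_causal
                else ("steiger-empty" if filtered.nsnp == 0 else ""))})
        if not excluded:
            candidates.append(pid)
    state["candidates"] = candidates
    pd.DataFrame(steiger_rows).to_csv(outdir / "steiger.tsv", sep="\t",
                                      index=False)
    pd.DataFrame(reverse_rows).to_csv(outdir / "reverse_mr.tsv", sep="\t",
                                      index=False)
    pd.DataFrame(final_rows).to_csv(outdir / "direction_summary.tsv",
                                    sep="\t", index=False)
    return len(hits), len(candidates)


def _stage_coloc(study, config, outdir, state):
    candidates = state["candidates"]
    results = coloc_all_hits(candidates, study.pqtl_tables, study.outcome,
                             study.anchors, window=config.coloc_window,
                             priors=config.priors(),
                             strong_threshold=config.pph4_strong,
                             moderate_low=config.pph4_moderate)
    state["coloc"] = results
    rows = []
    for pid, res in results.items():
        if res is None:
            rows.append({"protein": pid, "status": "untestable"})
            continue
        rows.append({"protein": pid, "status": "ok", "nsnps": res.nsnps,
                     "pph0": res.pph0, "pph1": res.pph1, "pph2": res.pph2,
                     "pph3": res.pph3, "pph4": res.pph4,
                     "support": res.support})
    pd.DataFrame(rows).to_csv(outdir / "coloc.tsv", sep="\t", index=False)
    with open(outdir / "coloc_priors.json", "w") as fh:
        json.dump(dataclasses.asdict(config.priors()), fh, indent=1)
    return len(candidates), len(rows)


def _stage_de(study, config, outdir, state):
    de_results: dict = {}
    n_in = n_out = 0
    for ds, (mat, labels) in study.expression.items():
        res = de_test(mat, labels, lfc_cutoff=config.de_lfc,
                      alpha=config.de_alpha)
        de_results[ds] = res
        res.to_csv(outdir / f"de_{ds}.tsv", sep="\t", index=False)
        n_in += mat.shape[0]
        n_out += int(res["significant"].sum())
    state["de"] = de_results
    names = list(de_results)
    if len(names) >= 2:
        conc = concordance(de_results[names[0]], de_results[names[1]])
        conc.to_csv(outdir / "de_concordance.tsv", sep="\t", index=False)
        state["de_concordance"] = conc
    return n_in, n_out


def _stage_evidence(study, config, outdir, state):
    candidates = state["candidates"]
    screen = state["screen"]
    coloc_res = state.get("coloc", {})
    de_results = state.get("de", {})
    edges = filter_ppi_edges(study.ppi_edges, config.ppi_min_score)

    def de_flags(pid):
        sig, signs = [], []
        for res in de_results.values():
            row = res[res["gene"] == pid]
            if len(row):
                sig.append(bool(row["significant"].iloc[0]))
                signs.append(float(row["log2fc"].iloc[0]))
        any_sig = any(sig)
        both_sig = len(sig) >= 2 and all(sig)
        lfc = signs[0] if signs else np.nan
        return any_sig, both_sig, lfc

    profiles, extra = [], []
    for pid in candidates:
        res = coloc_res.get(pid)
        coloc_strong = bool(res is not None
                            and res.pph4 > config.pph4_strong)
        any_sig, both_sig, lfc = de_flags(pid)
        connected = ppi_connectivity(pid, edges, study.drug_targets)
        prof = EvidenceProfile(pid, True, coloc_strong, any_sig, connected,
                               bool(study.druggable.get(pid, False)))
        profiles.append(prof)
        est = screen.results[pid].primary
        extra.append({"protein": pid, "de_both_datasets": both_sig,
                      "mr_de_direction": mr_de_direction_check(est.or_, lfc)
                      if np.isfinite(lfc) else "untested"})
    matrix = evidence_matrix(profiles)
    matrix = matrix.merge(pd.DataFrame(extra), on="protein", how="left") \
        if extra else matrix
    matrix.to_csv(outdir / "evidence.tsv", sep="\t", index=False)
    state["evidence"] = matrix
    return len(candidates), len(matrix)


def _stage_mediation(study, config, outdir, state):
    candidates = state["candidates"]
    screen = state["screen"]
    instruments = state["instruments"]
    proteins = {p: instruments[p] for p in candidates}
    factor_instruments = {}
    for fid, table in study.factor_tables.items():
        factor_instruments[fid] = select_instruments(
            table, p_max=config.p_max, cis=study.factor_regions.get(fid),
            mhc=MHC_GRCH37, ld=study.factor_ld.get(fid),
            r2_max=config.r2_max)
    totals = {p: (screen.results[p].primary.beta,
                  screen.results[p].primary.se) for p in candidates}
    results, screened, s1, s2 = run_two_step(
        proteins, factor_instruments, study.factor_tables, study.outcome,
        totals, seed=config.seed)
    state["mediation"] = (results, screened)
    mediation_frame(results).to_csv(outdir / "mediation.tsv", sep="\t",
                                    index=False)
    s1.to_csv(outdir / "mediation_step1.tsv", sep="\t", index=False)
    s2.to_csv(outdir / "mediation_step2.tsv", sep="\t", index=False)
    return len(results), len(screened)


def _stage_report(study, config, outdir, state):
    text = report(outdir)
    (outdir / "report.txt").write_text(text)
    return 1, 1


def report(outdir) -> str:
    """Human-readable summary of a finished (or partial) run directory:
    forest table, colocalization, tiers and mediators. Protective
    candidates (OR < 1) are annotated as agonist-direction targets,
    risk-increasing ones (OR > 1) as inhibitor-direction."""
    outdir = Path(outdir)
    lines = [f"protmr {__version__} run report", "=" * 34, ""]

    def load(name):
        p = outdir / name
        if not p.exists():
            return None
        try:
            return pd.read_csv(p, sep="\t")
        except pd.errors.EmptyDataError:
            return None

    screen = load("screen.tsv")
    evidence = load("evidence.tsv")
    coloc_t = load("coloc.tsv")
    med = load("mediation.tsv")

    if screen is not None and "primary" in screen:
        prim = screen[(screen["primary"] == True) # noqa: E712
                      & (screen["significant"] == True)]  # noqa: E712
        lines.append(f"MR-significant proteins: {len(prim)}")
        if len(prim) == 0:
            lines.append("zero candidates at the Bonferroni threshold")
        for _, r in prim.iterrows():
            direction = ("agonist-direction target" if r["or"] < 1
                         else "inhibitor-direction target"
                         if r["or"] > 1 else "direction indeterminate")
            lines.append(
                f"  {r['protein']:<10} OR={r['or']:.2f} "
                f"(95% CI {r['ci_low']:.2f}-{r['ci_high']:.2f}) "
                f"p={r['pval']:.2e} nsnp={int(r['nsnp'])} [{direction}]")
    else:
        lines.append("no screen output found")
    lines.append("")

    if coloc_t is not None and len(coloc_t):
        lines.append("Colocalization (PPH4):")
        for _, r in coloc_t.iterrows():
            if r.get("status") != "ok":
                lines.append(f"  {r['protein']:<10} untestable")
            else:
                lines.append(f"  {r['protein']:<10} PPH4={r['pph4']:.3f} "
                             f"support={r['support']}")
        lines.append("")

    if evidence is not None and len(evidence):
        lines.append("Evidence tiers:")
        for _, r in evidence.sort_values("tier").iterrows():
            flags = "".join("+" if r[c] else "-" for c in
                            ("coloc_strong", "de_significant",
                             "ppi_connected", "druggable"))
            lines.append(f"  tier {int(r['tier'])}  {r['protein']:<10} "
                         f"[coloc/DE/PPI/drug {flags}]")
        lines.append("")

    if med is not None and len(med):
        passing = med[med["passes_screen"] == True]  # noqa: E712
        lines.append(f"Mediators passing the two-step screen: {len(passing)}")
        for _, r in passing.iterrows():
            lines.append(
                f"  {r['protein']} -> {r['mediator']} -> outcome: "
                f"proportion mediated {r['proportion_pct']:.1f}%")
        lines.append("")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# study-directory IO (the TSV dialects the readers accept + truth JSON)

def write_study(study: StudyData, root) -> None:
    root = Path(root)
    for sub in ("pqtl", "ld", "expression", "factors"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    for pid, t in study.pqtl_tables.items():
        t.to_tsv(root / "pqtl" / f"{pid}.tsv")
        study.pqtl_ld[pid].to_csv(root / "ld" / f"{pid}.tsv", sep="\t")
    study.outcome.to_tsv(root / "outcome.tsv")
    study.outcome_ld.to_csv(root / "outcome_ld.tsv", sep="\t")
    pd.DataFrame([{"protein": p, "chrom": c, "tss": t}
                  for p, (c, t) in study.anchors.items()]
                 ).to_csv(root / "anchors.tsv", sep="\t", index=False)
    for ds, (mat, labels) in study.expression.items():
        mat.to_csv(root / "expression" / f"{ds}.matrix.tsv", sep="\t")
        pd.DataFrame({"sample": mat.columns, "group": labels}
                     ).to_csv(root / "expression" / f"{ds}.labels.tsv",
                              sep="\t", index=False)
    study.ppi_edges.to_csv(root / "ppi_edges.tsv", sep="\t", index=False)
    (root / "drug_targets.txt").write_text(
        "\n".join(study.drug_targets) + "\n")
    pd.DataFrame([{"protein": p, "druggable": v}
                  for p, v in study.druggable.items()]
                 ).to_csv(root / "druggability.tsv", sep="\t", index=False)
    for fid, t in study.factor_tables.items():
        t.to_tsv(root / "factors" / f"{fid}.tsv")
        study.factor_ld[fid].to_csv(root / "factors" / f"{fid}.ld.tsv",
                                    sep="\t")
    pd.DataFrame([{"factor": f, "chrom": r.chrom, "start": r.start,
                   "end": r.end}
                  for f, r in study.factor_regions.items()]
                 ).to_csv(root / "factor_regions.tsv", sep="\t", index=False)
    (root / "truth.json").write_text(study.truth.to_json())


def load_study(root) -> StudyData:
    root = Path(root)
    pqtl_tables, pqtl_ld = {}, {}
    for f in sorted((root / "pqtl").glob("*.tsv")):
        pid = f.stem
        pqtl_tables[pid] = make_table(pd.read_csv(f, sep="\t"), pid)
        pqtl_ld[pid] = pd.read_csv(root / "ld" / f"{pid}.tsv", sep="\t",
                                   index_col=0)
    outcome = make_table(pd.read_csv(root / "outcome.tsv", sep="\t"),
                         "outcome", "binary")
    outcome_ld = pd.read_csv(root / "outcome_ld.tsv", sep="\t", index_col=0)
    anchors = {r["protein"]: (str(r["chrom"]), int(r["tss"]))
               for _, r in pd.read_csv(root / "anchors.tsv",
                                       sep="\t").iterrows()}
    expression = {}
    for f in sorted((root / "expression").glob("*.matrix.tsv")):
        ds = f.name.replace(".matrix.tsv", "")
        mat = pd.read_csv(f, sep="\t", index_col=0)
        lab = pd.read_csv(root / "expression" / f"{ds}.labels.tsv",
                          sep="\t")["group"].tolist()
        expression[ds] = (mat, lab)
    ppi_edges = pd.read_csv(root / "ppi_edges.tsv", sep="\t")
    drug_targets = [ln for ln in
                    (root / "drug_targets.txt").read_text().splitlines()
                    if ln.strip()]
    druggable = {r["protein"]: bool(r["druggable"]) for _, r in
                 pd.read_csv(root / "druggability.tsv", sep="\t").iterrows()}
    factor_tables, factor_ld = {}, {}
    for f in sorted((root / "factors").glob("*.tsv")):
        if f.name.endswith(".ld.tsv"):
            continue
        fid = f.stem
        factor_tables[fid] = make_table(pd.read_csv(f, sep="\t"), fid)
        factor_ld[fid] = pd.read_csv(root / "factors" / f"{fid}.ld.tsv",
                                     sep="\t", index_col=0)
    factor_regions = {
        r["factor"]: RegionSpec(str(r["chrom"]), int(r["start"]),
                                int(r["end"]))
        for _, r in pd.read_csv(root / "factor_regions.tsv",
                                sep="\t").iterrows()}
    truth_file = root / "truth.json"
    truth = SimTruth(**json.loads(truth_file.read_text())) \
        if truth_file.exists() else SimTruth(seed=-1)
    return StudyData(pqtl_tables, pqtl_ld, outcome, outcome_ld, anchors,
                     expression, ppi_edges, drug_targets, druggable,
                     factor_tables, factor_regions, factor_ld, truth)
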