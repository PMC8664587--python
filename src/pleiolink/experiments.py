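"""Experiment presets and the replicate orchestrator.

Each preset reproduces one of the standard experimental grids — equilibrium
genetic correlation across mutation regimes and architectures, the effect of
within-pair and between-pair map distance, migration from a source deme, and
the association-mapping experiments on neutral SNP panels and biallelic
QTNs — at either ``full`` scale (the published parameterization: N=5000,
50,000 generations, 120 loci per trait, 10-50 replicates; cluster budget)
or ``reduced`` desk scale (N=500, 60 loci per trait, 5,000-10,000
generations, 10 replicates, 100-SNP panels on 20 chromosomes). Every knob
is overridable, which the test suite uses to shrink runs further.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import NeutralPanelSpec, build_architecture
from .gwaa import compute_grm, discovery_metrics, multivariate_scan, univariate_scan
from .mutation import CONTINUUM, MutationParams, QTN_BIALLELIC
from .popstats import segregating_counts
from .selection import build_selection
from .simulate import SimConfig, run_simulation

__all__ = ["PRESETS", "RunManifest", "full_scale_parameters", "run_experiment"]

PRESETS = ("fig3", "fig4", "fig5", "fig6", "table1", "table2", "table3")

_FOCAL_OPTIMA = (10.0, 10.0)
# source optimum 10 units from the focal optimum along the selection diagonal
_SOURCE_OPTIMA = (10.0 + 10.0 / np.sqrt(2.0), 10.0 + 10.0 / np.sqrt(2.0))


@dataclass
class _Scale:
    n_individuals: int
    generations: int
    n_loci: int
    replicates: int
    sample_size: int
    panel_snps: int
    panel_chroms: int  # loci per trait in panel (GWAA) runs
    migration_burn_in: int
    migration_generations: int
    # reduced-scale migration runs need high mutational input: with
    # negligible local variance a single rare migrant family saturates the
    # focal-deme correlation and the migration-rate ordering is lost
    migration_mu: float
    # neutral-panel per-allele rate; None = keep the full-scale population
    # parameter 4*N*mu = 0.02 at this N (coalescent rescaling)
    panel_neutral_mu: float | None


_FULL = _Scale(
    n_individuals=5000,
    generations=50000,
    n_loci=120,
    replicates=30,
    sample_size=1000,
    panel_snps=1000,
    panel_chroms=120,
    migration_burn_in=40000,
    migration_generations=10000,
    migration_mu=1e-5,
    panel_neutral_mu=1e-6,
)
_REDUCED = _Scale(
    n_individuals=500,
    generations=5000,
    n_loci=60,
    replicates=10,
    sample_size=500,
    panel_snps=100,
    panel_chroms=20,
    migration_burn_in=2000,
    migration_generations=2000,
    migration_mu=1e-3,
    panel_neutral_mu=None,
)

_GWAA_REPLICATES = {"full": 10, "reduced": 10}
_FIG6_REPLICATES = {"full": 50, "reduced": 10}


def full_scale_parameters() -> dict:
    """The published full-scale parameter tables, keyed by preset.

    Exposed so the parameterization can be asserted against directly.
    """
    return {
        "common": {
            "N": 5000,
            "generations": 50000,
            "n_loci_per_trait": 120,
            "optima": list(_FOCAL_OPTIMA),
            "sample_size": 1000,
        },
        "fig3": {
            "architectures": ["linkage", "pleiotropy"],
            "within_pair_cM": 0.0,
            "mu": [1e-3, 1e-4, 1e-5],
            "alpha2": [0.001, 0.1],
            "omega2": 100.0,
            "rho_omega": 0.9,
            "replicates": 30,
        },
        "fig4": {
            "within_pair_cM": [0.0, 0.1, 1.0],
            "panels": [
                {"omega2": 50.0, "rho_omega": 0.9},
                {"omega2": 100.0, "rho_omega": 0.9},
                {"omega2": 100.0, "rho_omega": 0.5},
            ],
            "regimes": [
                {"alpha2": 0.001, "mu": 1e-3},
                {"alpha2": 0.1, "mu": 1e-5},
            ],
        },
        "fig5": {
            "between_pair_cM": [0.001, 0.1, 1.0],
            "alpha2": 0.1,
            "mu": [1e-5, 1e-3],
            "omega2": 100.0,
            "rho_omega": 0.9,
        },
        "fig6": {
            "migration_rates": [0.001, 0.01, 0.1],
            "source_rho_omega": [0.0, 0.9],
            "focal_rho_omega": 0.0,
            "omega2": 100.0,
            "architectures": ["pleiotropy", "linkage:0", "linkage:0.1", "linkage:1"],
            "migration_generations": 10000,
            "replicates": 50,
        },
        "table1": {
            "neutral_per_chromosome": 1000,
            "panel_length_cM": 0.1,
            "neutral_mu": 1e-6,
            "fdr": 0.1,
            "window_cM": 0.05,
            "replicates": 10,
            "rows": _gwaa_rows(),
        },
        "table3": {
            "fdr": 0.1,
            "replicates": 10,
            "rows": _qtn_rows(),
        },
    }


def _gwaa_rows():
    """(kind, alpha2, mu, rho_omega) rows of the neutral-SNP scans."""
    rows = []
    for kind in ("linkage", "pleiotropy"):
        rows += [
            (kind, 0.001, 1e-3, 0.9),
            (kind, 0.1, 1e-3, 0.9),
            (kind, 0.001, 1e-5, 0.9),
        ]
        if kind == "linkage":
            rows.append((kind, 0.1, 1e-5, 0.9))
        else:
            rows.append((kind, 0.1, 1e-5, 0.06))
            rows.append((kind, 0.1, 1e-5, 0.9))
    return rows


def _qtn_rows():
    """(kind, alpha2, mu, rho_omega) rows of the biallelic-QTN scans."""
    return [
        ("linkage", 0.001, 1e-3, 0.9),
        ("linkage", 0.1, 1e-3, 0.9),
        ("linkage", 0.001, 1e-5, 0.9),
        ("linkage", 0.1, 1e-5, 0.9),
        ("pleiotropy", 0.001, 1e-3, 0.9),
        ("pleiotropy", 0.1, 1e-3, 0.85),
        ("pleiotropy", 0.001, 1e-5, 0.01),
        ("pleiotropy", 0.1, 1e-5, 0.01),
    ]


# ---------------------------------------------------------------------------
# replicate runners


def _sim_cell_config(
    kind, mu, alpha2, omega2, rho_omega, sc: _Scale, seed,
    within_pair=0.0, between_pair=None, n_loci=None,
):
    arch = build_architecture(
        kind, n_loci or sc.n_loci, within_pair_cM=within_pair, between_pair_cM=between_pair
    )
    return SimConfig(
        architecture=arch,
        mutation=MutationParams(mu=mu, alpha2=alpha2),
        selection=build_selection(omega2, rho_omega, _FOCAL_OPTIMA),
        n_individuals=sc.n_individuals,
        generations=sc.generations,
        sample_size=0,
        seed=seed,
    )


def _run_sim_cell(cell, sc, seed):
    cfg = _sim_cell_config(
        cell["architecture"], cell["mu"], cell["alpha2"], cell["omega2"],
        cell["rho_omega"], sc, seed,
        within_pair=cell.get("within_pair_cM", 0.0),
        between_pair=cell.get("between_pair_cM"),
    )
    res = run_simulation(cfg)
    last = res.trajectory.iloc[-1]
    return {
        "gcor": last["gcor"],
        "gvar1": last["gvar1"],
        "gvar2": last["gvar2"],
        "n_seg_causal": last["n_seg_causal"],
    }


def _run_migration_cell(cell, sc, seed):
    arch_kind = cell["architecture"]
    within = cell.get("within_pair_cM", 0.0)
    arch = build_architecture(arch_kind, sc.n_loci, within_pair_cM=within)
    mut = MutationParams(mu=cell["mu"], alpha2=cell["alpha2"])
    focal = SimConfig(
        architecture=arch,
        mutation=mut,
        selection=build_selection(cell["omega2"], cell["focal_rho_omega"], _FOCAL_OPTIMA),
        n_individuals=sc.n_individuals,
        generations=sc.migration_burn_in + sc.migration_generations,
        migration_rate=cell["m"],
        migration_start=sc.migration_burn_in,
        sample_size=0,
        seed=seed,
    )
    source = SimConfig(
        architecture=arch,
        mutation=mut,
        selection=build_selection(cell["omega2"], cell["source_rho_omega"], _SOURCE_OPTIMA),
        n_individuals=sc.n_individuals,
        generations=focal.generations,
        sample_size=0,
        seed=seed + 1,
    )
    res = run_simulation(focal, source_config=source)
    last = res.trajectory.iloc[-1]
    return {"gcor": last["gcor"], "gvar1": last["gvar1"], "gvar2": last["gvar2"]}


def _run_gwaa_cell(cell, sc, seed, multivariate: bool):
    neutral_mu = (
        sc.panel_neutral_mu
        if sc.panel_neutral_mu is not None
        else 0.02 / (4 * sc.n_individuals)
    )
    panel = NeutralPanelSpec(
        n_neutral_per_chromosome=sc.panel_snps,
        chromosome_length_cM=0.1,
        neutral_mu=neutral_mu,
    )
    arch = build_architecture(
        cell["architecture"], sc.panel_chroms, within_pair_cM=0.0, neutral_panel=panel
    )
    cfg = SimConfig(
        architecture=arch,
        mutation=MutationParams(mu=cell["mu"], alpha2=cell["alpha2"], neutral_mu=panel.neutral_mu),
        selection=build_selection(cell["omega2"], cell["rho_omega"], _FOCAL_OPTIMA),
        n_individuals=sc.n_individuals,
        generations=sc.generations,
        sample_size=sc.sample_size,
        seed=seed,
    )
    res = run_simulation(cfg)
    sample = res.sample
    counts = segregating_counts(res.population, arch)
    out = {
        "gcor": res.trajectory.iloc[-1]["gcor"],
        "n_qtl_segregating": counts["causal"],
        "n_snp_polymorphic": int((sample.maf() > 0).sum()),
    }
    if multivariate:
        K = compute_grm(sample.genotypes)
        scan = multivariate_scan(sample, K, fdr=cell.get("fdr", 0.1))
        rep = discovery_metrics(scan, sample.truth, window_cM=0.05, sample=sample)
        out.update(
            dr_pleio=rep.dr, snp_pleio=rep.snp_pleio, r2=rep.mean_r2,
        )
    else:
        s1 = univariate_scan(sample, 1, fdr=cell.get("fdr", 0.1))
        s2 = univariate_scan(sample, 2, fdr=cell.get("fdr", 0.1))
        rep = discovery_metrics((s1, s2), sample.truth, window_cM=0.05, sample=sample)
        out.update(
            dr_pleio=rep.dr_pleio, dr_single=rep.dr_single,
            snp_sig=rep.snp_sig, snp_pleio=rep.snp_pleio, r2=rep.mean_r2,
        )
    return out


def _run_qtn_cell(cell, sc, seed):
    arch = build_architecture(
        cell["architecture"], sc.n_loci, within_pair_cM=0.0, biallelic=True
    )
    cfg = SimConfig(
        architecture=arch,
        mutation=MutationParams(mu=cell["mu"], alpha2=cell["alpha2"], mode=QTN_BIALLELIC),
        selection=build_selection(cell["omega2"], cell["rho_omega"], _FOCAL_OPTIMA),
        n_individuals=sc.n_individuals,
        generations=sc.generations,
        sample_size=sc.sample_size,
        seed=seed,
    )
    res = run_simulation(cfg)
    sample = res.sample
    s1 = univariate_scan(sample, 1, fdr=cell.get("fdr", 0.1))
    s2 = univariate_scan(sample, 2, fdr=cell.get("fdr", 0.1))
    rep = discovery_metrics((s1, s2), sample.truth, window_cM=0.05, sample=sample)
    return {
        "gcor": res.trajectory.iloc[-1]["gcor"],
        "fpr": rep.fpr,
        "fnr": rep.fnr,
        "n_sign": rep.snp_sig,
        "n_pleio": rep.snp_pleio,
        "n_segr": rep.n_truth_segregating,
        "r2": rep.mean_r2,
    }


# ---------------------------------------------------------------------------
# preset cell grids


def _cells(preset: str, sc: _Scale) -> list[dict]:
    if preset == "fig3":
        return [
            {
                "architecture": kind, "mu": mu, "alpha2": a2,
                "omega2": 100.0, "rho_omega": 0.9, "runner": "sim",
            }
            for kind in ("linkage", "pleiotropy")
            for a2 in (0.001, 0.1)
            for mu in (1e-3, 1e-4, 1e-5)
        ]
    if preset == "fig4":
        cells = []
        for panel in ({"omega2": 50.0, "rho_omega": 0.9},
                      {"omega2": 100.0, "rho_omega": 0.9},
                      {"omega2": 100.0, "rho_omega": 0.5}):
            for a2, mu in ((0.001, 1e-3), (0.1, 1e-5)):
                for d in (0.0, 0.1, 1.0):
                    cells.append({
                        "architecture": "linkage", "within_pair_cM": d,
                        "mu": mu, "alpha2": a2, "runner": "sim", **panel,
                    })
                cells.append({
                    "architecture": "pleiotropy", "mu": mu, "alpha2": a2,
                    "runner": "sim", **panel,
                })
        return cells
    if preset == "fig5":
        cells = [
            {
                "architecture": "linkage", "between_pair_cM": d,
                "mu": mu, "alpha2": 0.1, "omega2": 100.0, "rho_omega": 0.9,
                "runner": "sim",
            }
            for mu in (1e-5, 1e-3)
            for d in (0.001, 0.1, 1.0)
        ]
        cells.append({
            "architecture": "pleiotropy", "mu": 1e-5, "alpha2": 0.1,
            "omega2": 100.0, "rho_omega": 0.9, "runner": "sim",
        })
        return cells
    if preset == "fig6":
        cells = []
        for src_rho in (0.0, 0.9):
            for arch in ("pleiotropy", "linkage:0", "linkage:0.1", "linkage:1"):
                kind, _, dist = arch.partition(":")
                for m in (0.001, 0.01, 0.1):
                    cells.append({
                        "architecture": kind,
                        "within_pair_cM": float(dist) if dist else 0.0,
                        "m": m, "source_rho_omega": src_rho, "focal_rho_omega": 0.0,
                        "omega2": 100.0, "mu": sc.migration_mu, "alpha2": 0.1,
                        "runner": "migration",
                    })
        return cells
    if preset in ("table1", "table2"):
        return [
            {
                "architecture": kind, "alpha2": a2, "mu": mu,
                "omega2": 100.0, "rho_omega": rho, "fdr": 0.1,
                "runner": "gwaa_multi" if preset == "table1" else "gwaa_uni",
            }
            for kind, a2, mu, rho in _gwaa_rows()
        ]
    if preset == "table3":
        return [
            {
                "architecture": kind, "alpha2": a2, "mu": mu,
                "omega2": 100.0, "rho_omega": rho, "fdr": 0.1, "runner": "qtn",
            }
            for kind, a2, mu, rho in _qtn_rows()
        ]
    raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")


@dataclass
class RunManifest:
    """Traceability record for one experiment invocation.

    Every output row maps back to a (config hash, replicate seed) pair;
    the hash covers the preset, scale and all overrides.
    """

    preset: str
    scale: str
    config_hash: str
    seeds: list
    software_version: str
    wall_clock_s: float = 0.0
    per_replicate_s: list = field(default_factory=list)


def _config_hash(preset, scale, sc) -> str:
    blob = json.dumps({"preset": preset, "scale": scale, **sc.__dict__},
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


_RUNNERS = {
    "sim": _run_sim_cell,
    "migration": _run_migration_cell,
    "gwaa_multi": lambda c, sc, s: _run_gwaa_cell(c, sc, s, True),
    "gwaa_uni": lambda c, sc, s: _run_gwaa_cell(c, sc, s, False),
    "qtn": _run_qtn_cell,
}


def run_experiment(
    preset: str,
    scale: str = "reduced",
    seeds=None,
    overrides: dict | None = None,
    on_error: str = "report",
) -> pd.DataFrame:
    """Run a preset's replicate grid and aggregate per-cell means and SDs.

    ``seeds`` lists the replicate seeds (defaults to 0..replicates-1); every
    (cell, seed) pair maps to a unique simulator seed so runs are exactly
    reproducible. Replicates that fail are reported and skipped when
    ``on_error="report"`` (the run continues), or re-raised with "raise".
    """
    if scale not in ("full", "reduced"):
        raise ValueError("scale must be 'full' or 'reduced'")
    sc_base = _FULL if scale == "full" else _REDUCED
    sc = _Scale(**{**sc_base.__dict__, **(overrides or {})})
    if preset in ("table1", "table2", "table3"):
        default_reps = _GWAA_REPLICATES[scale]
    elif preset == "fig6":
        default_reps = _FIG6_REPLICATES[scale]
    else:
        default_reps = sc.replicates
    if seeds is None:
        seeds = list(range(default_reps if "replicates" not in (overrides or {})
                           else sc.replicates))

    from . import __version__

    manifest = RunManifest(preset, scale, _config_hash(preset, scale, sc),
                           list(seeds), __version__)
    t_start = time.time()
    rows = []
    for ci, cell in enumerate(_cells(preset, sc)):
        runner = _RUNNERS[cell["runner"]]
        for seed in seeds:
            full_seed = (int(seed) * 1009 + ci * 97 + 1) % (2**31 - 1)
            t0 = time.time()
            try:
                metrics = runner(cell, sc, full_seed)
            except Exception as exc:  # pragma: no cover - partial failure path
                if on_error == "raise":
                    raise
                metrics = {"error": str(exc)}
                print(f"[{manifest.config_hash}] cell {ci} seed {seed} "
                      f"failed: {exc}", file=sys.stderr)
            manifest.per_replicate_s.append(round(time.time() - t0, 3))
            rows.append({
                **{k: v for k, v in cell.items() if k != "runner"},
                "replicate_seed": seed, "config_hash": manifest.config_hash,
                **metrics,
            })
    manifest.wall_clock_s = round(time.time() - t_start, 3)
    raw = pd.DataFrame(rows)
    keys = [k for k in ("architecture", "within_pair_cM", "between_pair_cM",
                        "mu", "alpha2", "omega2", "rho_omega", "m",
                        "source_rho_omega") if k in raw.columns]
    metrics = [c for c in raw.columns
               if c not in keys + ["replicate_seed", "fdr", "error"]
               and raw[c].dtype.kind in "fi"]
    agg = raw.groupby(keys, dropna=False)[metrics].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    agg = agg.reset_index()
    agg.attrs["replicates"] = raw
    agg.attrs["manifest"] = manifest
    return agg
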