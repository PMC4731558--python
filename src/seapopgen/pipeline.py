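"""End-to-end orchestration: read inputs, run every analysis stage, emit
paper-style CSV reports plus a JSON manifest (seed, config hash, producer
per output)."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import dispersal as disp
from . import msat, mtdna, seascape
from .io import (
    MatrixTable,
    read_fasta_alignment,
    read_genepop,
    read_locality_csv,
    read_matrix_csv,
    write_matrix_csv,
)

logger = logging.getLogger("seapopgen")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Run settings; file paths plus the knobs of every stage."""

    fasta: Optional[str] = None
    genepop: Optional[str] = None
    localities: Optional[str] = None
    shipping: Optional[str] = None
    velocity: Optional[str] = None
    out_dir: str = "results"
    seed: int = 1
    n_perm: int = 10_000
    n_sim: int = 10_000
    fdr_alpha: float = 0.05
    rarefaction_g: int = 34
    gamma_alpha: float = 0.023
    distance_model: str = "tn93"
    mantel_perm: int = 1000
    generations: tuple[int, ...] = (16, 32)
    particles_per_locality: int = 47040
    pld_days: tuple[float, float] = (20.0, 30.0)
    dt_minutes: float = 15.0
    years: int = 8
    spawning_window: tuple[int, int] = (152, 243)
    releases_per_window: int = 8
    n_boot: int = 1000

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        data = tomllib.loads(Path(path).read_text())
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("generations", "pld_days", "spawning_window"):
            if key in known:
                known[key] = tuple(known[key])
        return cls(**known)

    def digest(self) -> str:
        return hashlib.sha256(repr(sorted(self.__dict__.items())).encode()).hexdigest()[:16]


def report_diversity(
    haplotable: mtdna.HaplotypeTable,
    msat_table=None,
    model: mtdna.DistanceModel | None = None,
    rarefaction_g: int = 34,
) -> pd.DataFrame:
    """Per-population diversity table (sample sizes, haplotype counts,
    private-haplotype ratio, h, pi, and the microsatellite He/Ho/Ar means).

    Rounding: priv/N 2 decimals, h 3 decimals, pi 4 decimals.
    """
    rows = []
    msat_stats = None
    ar = None
    if msat_table is not None:
        msat_stats = msat.locus_pop_stats(msat_table)
        try:
            ar = msat.allelic_richness(msat_table, g=rarefaction_g)
        except mtdna.UndefinedStatistic:
            ar = None
    for pop in haplotable.populations:
        n = haplotable.n(pop)
        counts = haplotable.pop_counts(pop)
        n_hap = int(np.sum(counts > 0))
        priv = haplotable.private_haplotypes(pop)
        row = {
            "population": pop,
            "N": n,
            "n_haplotypes": n_hap,
            "n_private": priv,
            "priv_per_N": round(priv / n, 2) if n else np.nan,
            "h": round(mtdna.haplotype_diversity(counts), 3) if n >= 2 else np.nan,
            "pi": round(mtdna.nucleotide_diversity(haplotable, model, pop), 4)
            if n >= 2 else np.nan,
        }
        if msat_stats is not None and pop in set(msat_stats["population"]):
            sub = msat_stats[msat_stats["population"] == pop]
            row["He"] = round(float(sub["He"].mean()), 3)
            row["Ho"] = round(float(sub["Ho"].mean()), 3)
            if ar is not None:
                row["Ar"] = round(
                    float(ar[ar["population"] == pop]["Ar"].mean()), 1
                )
        rows.append(row)
    rows.append({
        "population": "TOTAL",
        "N": int(haplotable.counts.sum()),
        "n_haplotypes": len(haplotable.haplotypes),
    })
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Run every stage the inputs allow and write the report bundle.

    Returns the manifest dictionary.  Any stage failure raises
    ``StageError`` after writing the manifest with an "incomplete" marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in config.__dict__.items()},
        "outputs": {},
        "notices": [],
        "complete": False,
    }

    def emit(name: str, producer: str) -> Path:
        manifest["outputs"][name] = producer
        return out / name

    stage = "read-inputs"
    try:
        localities = read_locality_csv(config.localities) if config.localities else None
        model = mtdna.DistanceModel(
            config.distance_model,
            alpha=config.gamma_alpha if config.distance_model == "tn93" else None,
        )
        haplotable = None
        if config.fasta:
            aln = read_fasta_alignment(
                config.fasta,
                population_map={},
                unknown_policy="unknown",
            )
            # population label is the sample-id prefix (<locality>_<k>)
            aln.population = [i.rsplit("_", 1)[0] for i in aln.ids]
            haplotable = mtdna.collapse_haplotypes(aln)
        geno = read_genepop(config.genepop) if config.genepop else None

        stage = "mtdna"
        if haplotable is not None:
            div = report_diversity(
                haplotable, geno, model=mtdna.DistanceModel("hamming"),
                rarefaction_g=config.rarefaction_g,
            )
            div.to_csv(emit("diversity.csv", "report_diversity"), index=False)
            if len(haplotable.populations) >= 2:
                phi = mtdna.pairwise_phist(
                    haplotable, model, n_perm=config.n_perm, seed=config.seed
                )
                write_matrix_csv(phi, emit("phist.csv", "pairwise_phist"))
                iu = np.triu_indices(len(phi.labels), k=1)
                reject, p_adj, thr = mtdna.fdr_adjust(
                    phi.pvalues[iu], alpha=config.fdr_alpha
                )
                pd.DataFrame({
                    "pair": [f"{phi.labels[i]}-{phi.labels[j]}" for i, j in zip(*iu)],
                    "phist": phi.values[iu],
                    "p": phi.pvalues[iu],
                    "p_fdr": p_adj,
                    "significant": reject,
                }).to_csv(emit("phist_fdr.csv", "fdr_adjust"), index=False)
            else:
                manifest["notices"].append(
                    "single population: differentiation stages skipped"
                )
            if localities is not None and len(set(localities.group)) >= 2:
                groups = dict(zip(localities.names, localities.group))
                if set(haplotable.populations) <= set(groups):
                    am = mtdna.amova_hierarchical(
                        haplotable, groups, model,
                        n_perm=config.n_perm, seed=config.seed,
                    )
                    pd.DataFrame([am.__dict__]).to_csv(
                        emit("amova.csv", "amova_hierarchical"), index=False
                    )
            neut_rows = []
            for pop in haplotable.populations:
                if haplotable.n(pop) < 4:
                    continue
                hist = mtdna.mismatch_distribution(haplotable, pop)
                fit = mtdna.fit_sudden_expansion(
                    hist, n_boot=config.n_boot, seed=config.seed,
                    sample_size=haplotable.n(pop),
                )
                d = mtdna.tajimas_d(haplotable, pop, n_sim=config.n_sim, seed=config.seed)
                fs = mtdna.fus_fs(haplotable, pop, n_sim=config.n_sim, seed=config.seed)
                neut_rows.append({
                    "population": pop, "tau": fit.tau, "theta0": fit.theta0,
                    "theta1": fit.theta1, "SSD": fit.ssd, "p_SSD": fit.p_ssd,
                    "raggedness": fit.raggedness, "p_raggedness": fit.p_raggedness,
                    "tajimas_D": d.statistic if d.defined else np.nan,
                    "p_D": d.p, "fus_Fs": fs.statistic if fs.defined else np.nan,
                    "p_Fs": fs.p, "S": d.s,
                })
            if neut_rows:
                pd.DataFrame(neut_rows).to_csv(
                    emit("mismatch_neutrality.csv", "fit_sudden_expansion/tajimas_d/fus_fs"),
                    index=False,
                )
            edges = mtdna.haplotype_mst(haplotable)
            pd.DataFrame(edges, columns=["source", "target", "steps"]).to_csv(
                emit("mst_edges.tsv", "haplotype_mst"), sep="\t", index=False
            )

        stage = "msat"
        theta_ena_mat = None
        if geno is not None:
            msat.locus_pop_stats(geno).to_csv(
                emit("msat_locus_stats.csv", "locus_pop_stats"), index=False
            )
            nulls = msat.null_allele_table(geno)
            nulls.to_csv(emit("null_alleles.csv", "null_allele_em"))
            if len(geno.populations) >= 2:
                theta_mat = msat.pairwise_theta(
                    geno, n_perm=min(config.n_perm, 1000), seed=config.seed
                )
                write_matrix_csv(theta_mat, emit("theta.csv", "theta_fst"))
                theta_ena_mat = msat.pairwise_theta_ena(geno, nulls)
                write_matrix_csv(theta_ena_mat, emit("theta_ena.csv", "theta_fst_ena"))
            bn_rows = []
            for pop in geno.populations:
                try:
                    bn = msat.bottleneck_test(
                        geno, pop, n_iter=min(config.n_sim, 2000), seed=config.seed
                    )
                    bn_rows.append({"population": pop, "p_excess": bn.p_excess})
                except mtdna.UndefinedStatistic as e:
                    manifest["notices"].append(f"bottleneck {pop}: {e}")
            if bn_rows:
                pd.DataFrame(bn_rows).to_csv(
                    emit("bottleneck.csv", "bottleneck_test"), index=False
                )

        stage = "dispersal"
        conn_min = None
        if config.velocity and localities is not None and localities.habitat_cells:
            vfield = disp.VelocityField.load(config.velocity)
            habitat = {
                n: [tuple(c) for c in cells]
                for n, cells in zip(localities.names, localities.habitat_cells)
            }
            spec = disp.ReleaseSpec(
                localities=habitat,
                particles_per_locality=config.particles_per_locality,
                pld_days=config.pld_days,
                dt_minutes=config.dt_minutes,
                years=config.years,
                spawning_window=config.spawning_window,
                releases_per_window=config.releases_per_window,
            )
            endpoints = disp.advect(vfield, spec, seed=config.seed)
            C = disp.connectivity(endpoints, habitat, vfield)
            write_matrix_csv(C, emit("connectivity.csv", "connectivity"))
            for g in config.generations:
                Cg = disp.multigeneration(C, g)
                write_matrix_csv(Cg, emit(f"connectivity_g{g}.csv", "multigeneration"))
                Cm = disp.symmetrize_min(Cg)
                write_matrix_csv(Cm, emit(f"connectivity_g{g}_min.csv", "symmetrize_min"))
                conn_min = Cm

        stage = "seascape"
        shipping = read_matrix_csv(config.shipping, symmetric=True) if config.shipping else None
        gen_mats: list[tuple[str, MatrixTable]] = []
        if haplotable is not None and len(haplotable.populations) >= 4:
            phi_lin = MatrixTable(
                labels=phi.labels,
                values=np.vectorize(mtdna.slatkin_linearize)(phi.values),
                symmetric=True,
            )
            gen_mats.append(("coi", phi_lin))
        if theta_ena_mat is not None and len(theta_ena_mat.labels) >= 4:
            th_lin = MatrixTable(
                labels=theta_ena_mat.labels,
                values=np.vectorize(mtdna.slatkin_linearize)(theta_ena_mat.values),
                symmetric=True,
            )
            gen_mats.append(("msat", th_lin))
        mantel_rows = []
        for name, gmat in gen_mats:
            if shipping is not None and shipping.labels == gmat.labels:
                res, tab = seascape.ibd_report(
                    gmat, shipping, n_perm=config.mantel_perm, seed=config.seed
                )
                tab.to_csv(emit(f"ibd_pairs_{name}.csv", "ibd_report"), index=False)
                mantel_rows.append(
                    {"test": f"ibd_{name}", "r": res.r, "p": res.p, "tail": res.tail}
                )
            if conn_min is not None and conn_min.labels == gmat.labels:
                res, tab = seascape.connectivity_report(
                    gmat, conn_min, n_perm=config.mantel_perm, seed=config.seed
                )
                tab.to_csv(
                    emit(f"connectivity_pairs_{name}.csv", "connectivity_report"),
                    index=False,
                )
                mantel_rows.append(
                    {"test": f"connectivity_{name}", "r": res.r, "p": res.p, "tail": res.tail}
                )
        if mantel_rows:
            pd.DataFrame(mantel_rows).to_csv(emit("mantel.csv", "mantel"), index=False)

        manifest["complete"] = True
    except Exception as e:  # noqa: BLE001 - converted to stage-named error
        manifest["notices"].append(f"incomplete: stage {stage} failed: {e}")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise StageError(stage, e) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
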