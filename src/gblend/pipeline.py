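"""End-to-end pipeline driver.

Strings together simulate -> QC -> GWA -> chip construction -> relationship
matrices -> lambda profiles (LDA: G_LD vs A; LDLA: G_LD vs G_LA) ->
test-set accuracy and bias, writing every intermediate artifact plus a
manifest with the seed, config hash and file hashes so a run can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import GenotypeMatrix, Pedigree
from .evaluate import evaluate_predictions
from .io import (
    write_genotypes,
    write_matrix,
    write_pedigree_csv,
    write_phenotypes_csv,
)
from .mixedmodel import predict_ebv, profile_lambda, reml_fit
from .panels import QcThresholds, qc_filter, run_gwa, select_esm_panel, select_gwam_panel
from .relmat import build_A, build_GLA, build_GLD, infer_transmissions
from .simulate import SimulationConfig, simulate_population, split_trn_tst

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    outdir: str = "run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    n_per_chromosome: int = 1000
    panels: tuple[str, ...] = ("ESM", "GWAM")
    lambda_step: float = 0.1
    fraction_trn: float = 3146 / 5416
    h2_eval: float | None = None  # None: use the pedigree-REML estimate

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        qc = QcThresholds(**raw.pop("qc", {}))
        if "panels" in raw:
            raw["panels"] = tuple(raw["panels"])
        return cls(simulation=sim, qc=qc, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["founder_maf_range"] = list(
            d["simulation"]["founder_maf_range"]
        )
        d["panels"] = list(d["panels"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; halt on failure, keeping prior artifacts on disk.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    manifest: dict = {
        "seed": config.seed,
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": [],
    }
    stage = "start"

    def done(name: str, t0: float) -> None:
        manifest["stages"].append({"stage": name, "seconds": round(time.time() - t0, 3)})
        log.info("stage %s done (%.1fs)", name, time.time() - t0)

    try:
        stage = "simulate"
        t0 = time.time()
        pop = simulate_population(config.simulation, seed=config.seed)
        ped: Pedigree = pop.pedigree
        subset = split_trn_tst(ped, config.fraction_trn, seed=config.seed + 3)
        phen = pop.phenotypes.copy()
        phen["subset"] = subset.loc[phen["id"]].to_numpy()
        geno: GenotypeMatrix = pop.marker_genotypes()
        write_pedigree_csv(ped, out / "pedigree.csv")
        write_phenotypes_csv(phen, out / "phenotypes.csv")
        artifacts += [out / "pedigree.csv", out / "phenotypes.csv"]
        artifacts += write_genotypes(geno, out / "genotypes", "plink_text")
        done(stage, t0)

        stage = "qc"
        t0 = time.time()
        geno_qc, report = qc_filter(geno, config.qc)
        (out / "qc_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        artifacts.append(out / "qc_report.json")
        done(stage, t0)

        stage = "gwa"
        t0 = time.time()
        gwa = run_gwa(geno_qc, phen.loc[phen["subset"] == "TRN"])
        gwa.to_csv(out / "gwa_results.tsv", sep="\t", index=False)
        artifacts.append(out / "gwa_results.tsv")
        done(stage, t0)

        stage = "panels"
        t0 = time.time()
        maf_tbl = geno_qc.markers.assign(maf=geno_qc.maf())
        chip_panels = {}
        if "ESM" in config.panels:
            chip_panels["ESM"] = select_esm_panel(maf_tbl, config.n_per_chromosome)
        if "GWAM" in config.panels:
            chip_panels["GWAM"] = select_gwam_panel(gwa, config.n_per_chromosome)
        for name, panel in chip_panels.items():
            p = out / f"panel_{name.lower()}.txt"
            p.write_text("\n".join(map(str, panel.markers)) + "\n")
            artifacts.append(p)
        done(stage, t0)

        stage = "relmat"
        t0 = time.time()
        A = build_A(ped)
        artifacts += write_matrix(A, out / "A.tsv")
        matrices = {}
        for name, panel in chip_panels.items():
            sub = geno_qc.subset_markers(panel.markers)
            order = np.argsort(
                sub.markers[["chrom", "cM"]].apply(tuple, axis=1).to_numpy()
            )
            sub = GenotypeMatrix(
                sub.ids, sub.counts[:, order], sub.markers.iloc[order]
            )
            gld = build_GLD(sub)
            trans = infer_transmissions(ped, sub)
            gla = build_GLA(ped, trans)
            matrices[name] = {"GLD": gld, "GLA": gla}
            artifacts += write_matrix(gld, out / f"GLD_{name.lower()}.tsv")
            artifacts += write_matrix(gla, out / f"GLA_{name.lower()}.tsv")
        done(stage, t0)

        stage = "profile"
        t0 = time.time()
        trn_phen = phen.loc[phen["subset"] == "TRN"]
        ped_fit = reml_fit(trn_phen, A)
        h2_eval = config.h2_eval if config.h2_eval is not None else ped_fit.h2
        profiles = {}
        for name, mats in matrices.items():
            for seq, M2 in (("LDA", A), ("LDLA", mats["GLA"])):
                prof = profile_lambda(
                    mats["GLD"], M2, trn_phen, config.lambda_step, sequence=seq
                )
                profiles[(name, seq)] = prof
                p = out / f"profile_{name.lower()}_{seq.lower()}.tsv"
                prof.table.to_csv(p, sep="\t", index=False, float_format="%.6g")
                artifacts.append(p)
        done(stage, t0)

        stage = "evaluate"
        t0 = time.time()
        rows = []
        for (name, seq), prof in profiles.items():
            mats = matrices[name]
            M2 = A if seq == "LDA" else mats["GLA"]
            for lam, fit in prof.fits.items():
                from .relmat import blend

                Mfull = blend(mats["GLD"], M2, lam)
                ebv = predict_ebv(fit, Mfull)
                res = evaluate_predictions(ebv, phen, h2_eval)
                rows.append(
                    {
                        "chip": name,
                        "sequence": seq,
                        "lambda": lam,
                        "accuracy": res.empirical_accuracy,
                        "residual_correlation": res.residual_correlation,
                        "bias": res.bias_coefficient,
                        "bias_se": res.bias_se,
                        "n_tst": res.n_tst,
                        "h2_used": res.h2_used,
                    }
                )
        eval_tbl = pd.DataFrame(rows)
        p = out / "evaluation.tsv"
        eval_tbl.to_csv(p, sep="\t", index=False, float_format="%.6g")
        artifacts.append(p)
        done(stage, t0)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["files"] = {
        str(p.relative_to(out)): _sha256(p) for p in artifacts if p.exists()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
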