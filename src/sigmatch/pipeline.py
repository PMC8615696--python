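"""End-to-end orchestration of the signature-matching screen.

Stages, in the paper-order the screen fixes: build (or load) drug
signatures -> Jaccard reversal scoring against the disease up-genes ->
top-k shortlist -> MOA enrichment of the shortlist -> BBB re-ranking to
the retained top-n -> per-candidate overlap report. Tables go to files,
logs to stderr, and a manifest records enough to reproduce bit-exact.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, bbb_screen, data_io, enrichment, matching, signatures

logger = logging.getLogger("sigmatch")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and parameters for one screen run.

    ``library_mode`` is ``sets`` (up/down GMT pair) or ``expression``
    (directory of GCT files named <signature_id>.gct with
    <signature_id>.classes.tsv sidecars).
    """

    disease_up_gmt: str
    metadata_tsv: str
    moa_tsv: str
    bbb_tsv: str
    outdir: str
    library_mode: str = "sets"
    disease_down_gmt: str | None = None
    library_up_gmt: str | None = None
    library_down_gmt: str | None = None
    experiments_dir: str | None = None
    gene_sets_gmt: str | None = None
    gamma: float = signatures.DEFAULT_GAMMA
    alpha: float = signatures.DEFAULT_ALPHA
    top_k: int = 100
    retain_n: int = 10
    symmetric: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.top_k < self.retain_n:
            raise ValueError(f"top_k={self.top_k} < retain_n={self.retain_n}")
        if self.library_mode not in ("sets", "expression"):
            raise ValueError(f"unknown library_mode {self.library_mode!r}")
        if self.library_mode == "sets" and not self.library_down_gmt:
            raise ValueError("sets mode needs library_down_gmt")
        if self.library_mode == "expression" and not self.experiments_dir:
            raise ValueError("expression mode needs experiments_dir")
        required = [self.disease_up_gmt, self.metadata_tsv, self.moa_tsv, self.bbb_tsv]
        optional = [
            self.disease_down_gmt,
            self.library_up_gmt,
            self.library_down_gmt,
            self.experiments_dir,
            self.gene_sets_gmt,
        ]
        for p in required + [q for q in optional if q]:
            if not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_disease_signatures(config: PipelineConfig) -> list[signatures.DiseaseSignature]:
    up = data_io.read_gmt(config.disease_up_gmt)
    down = data_io.read_gmt(config.disease_down_gmt) if config.disease_down_gmt else None
    return signatures.disease_signatures_from_gmt(up, down)


def load_library(config: PipelineConfig) -> list[signatures.Signature]:
    metadata = data_io.read_metadata_table(config.metadata_tsv)
    if config.library_mode == "sets":
        up = (
            data_io.read_gmt(config.library_up_gmt)
            if config.library_up_gmt
            else data_io.GeneSetLibrary([])
        )
        down = data_io.read_gmt(config.library_down_gmt)
        return signatures.library_from_gmt_pair(up, down, metadata)
    exp_dir = Path(config.experiments_dir)
    experiments = {}
    for gct in sorted(exp_dir.glob("*.gct")):
        sig_id = gct.stem
        experiments[sig_id] = data_io.read_gct(gct, exp_dir / f"{sig_id}.classes.tsv")
    if not experiments:
        raise FileNotFoundError(f"no .gct files under {exp_dir}")
    return signatures.build_signature_library(
        experiments, metadata, gamma=config.gamma, alpha=config.alpha
    )


def run_screen(config: PipelineConfig) -> dict[str, object]:
    """Run the full screen; write tables and a manifest under ``outdir``.

    Returns the in-memory results: reversal table, top-k table, MOA
    enrichment table, BBB-screened table, and the manifest dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "version": __version__,
        "stages": {},
        "complete": False,
    }
    results: dict[str, object] = {"manifest": manifest}

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            value = fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, outdir)
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
        }
        return value

    disease = stage("load_disease", lambda: load_disease_signatures(config))
    library = stage("build_signatures", lambda: load_library(config))
    logger.info(
        "loaded %d disease signature(s), %d drug signature(s)", len(disease), len(library)
    )

    scores = stage(
        "match",
        lambda: matching.score_library(disease, library, symmetric=config.symmetric),
    )
    logger.info("scored %d drug(s)", len(scores))
    matching.write_score_table(scores, outdir / "reversal_scores.tsv")

    k = min(config.top_k, len(scores))
    shortlist = stage("top_k", lambda: matching.top_k(scores, k))
    matching.write_score_table(shortlist, outdir / "top_k.tsv")

    moa_table = pd.read_csv(config.moa_tsv, sep="\t", dtype=str)
    annotations = enrichment.moa_annotations(moa_table)
    background = set(scores["drug_id"].astype(str))
    moa_enrich = stage(
        "moa_enrichment",
        lambda: enrichment.term_enrichment(
            set(shortlist["drug_id"].astype(str)) & background, annotations, background
        ),
    )
    enrichment.write_enrichment_table(moa_enrich, outdir / "moa_enrichment.tsv")

    bbb_scores = bbb_screen.read_bbb_table(config.bbb_tsv)
    retained = stage(
        "bbb_screen",
        lambda: bbb_screen.screen_by_bbb(shortlist, bbb_scores, config.retain_n),
    )
    logger.info("retained %d candidate(s) after BBB screen", len(retained))
    bbb_screen.write_bbb_table(retained, outdir / "bbb_top.tsv")

    manifest["complete"] = True
    manifest["counts"] = {
        "disease_signatures": len(disease),
        "drug_signatures": len(library),
        "drugs_scored": len(scores),
        "shortlist": len(shortlist),
        "retained": len(retained),
    }
    _write_manifest(manifest, outdir)

    results.update(
        reversal_scores=scores,
        top_k=shortlist,
        moa_enrichment=moa_enrich,
        bbb_top=retained,
        disease_signatures=disease,
        library=library,
    )
    return results


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def candidate_overlap_report(
    drug_id: str,
    disease: list[signatures.DiseaseSignature],
    library: list[signatures.Signature],
    gene_sets: data_io.GeneSetLibrary | None = None,
) -> dict[str, object]:
    """Overlap statistics between one candidate drug and the disease DEGs.

    For each disease signature the candidate's best-scoring condition is
    analyzed: overlap counts and upper-tail hypergeometric p for
    candidate-down vs disease-up (the reversal direction) and
    candidate-up vs disease-down, over the shared gene universe. If
    ``gene_sets`` is given, the reversal-overlap genes are tested for term
    enrichment against it.
    """
    mine = [s for s in library if s.drug_id == drug_id]
    if not mine:
        known = sorted({s.drug_id for s in library})
        near = difflib.get_close_matches(drug_id, known, n=5)
        raise KeyError(f"unknown drug {drug_id!r}; nearest: {near}")
    report: dict[str, object] = {"drug_id": drug_id, "per_disease": []}
    all_overlap: set[str] = set()
    for dis in disease:
        best_sig, best_score = None, -1.0
        for sig in mine:
            common = dis.gene_universe & set(sig.gene_universe)
            up, dn = dis.up_set & common, sig.down_set & common
            s = matching.jaccard(up, dn) if (up or dn) else 0.0
            if s > best_score:
                best_sig, best_score = sig, s
        assert best_sig is not None
        common = dis.gene_universe & set(best_sig.gene_universe)
        up, dn = dis.up_set & common, best_sig.down_set & common
        overlap = up & dn
        all_overlap |= overlap
        N = len(common)
        rev_p = (
            enrichment.hypergeometric_overlap_p(len(overlap), len(up), len(dn), N)
            if N
            else 1.0
        )
        d_dn, s_up = dis.down_set & common, best_sig.up_set & common
        mim = d_dn & s_up
        mim_p = (
            enrichment.hypergeometric_overlap_p(len(mim), len(d_dn), len(s_up), N)
            if N
            else 1.0
        )
        report["per_disease"].append(
            {
                "disease": dis.name,
                "signature_id": best_sig.signature_id,
                "jaccard": best_score,
                "universe": N,
                "reversal": {
                    "k": len(overlap),
                    "n_disease_up": len(up),
                    "n_drug_down": len(dn),
                    "p_value": rev_p,
                    "genes": sorted(overlap),
                },
                "mimicry": {
                    "k": len(mim),
                    "n_disease_down": len(d_dn),
                    "n_drug_up": len(s_up),
                    "p_value": mim_p,
                },
            }
        )
    if gene_sets is not None and all_overlap:
        universe = set()
        for dis in disease:
            universe |= dis.gene_universe
        enr = enrichment.term_enrichment(
            all_overlap & universe, gene_sets.as_dict(), universe
        )
        report["overlap_enrichment"] = enr.to_dict(orient="records")
    return report
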