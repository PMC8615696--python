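"""Synthetic LINCS-like inputs with planted ground truth.

Emulates, at desk scale, every input the screen consumes: a landmark-size
gene universe (~10^3 genes), a pair of disease up/down signatures sharing
a configurable fraction of up-genes, a multi-condition drug library in
which a few planted "reversal" drugs have down-sets overlapping the
disease up-genes at a controlled rate while background drugs overlap at a
much lower rate, a mechanism-of-action (MOA) table with one planted
enriched class, and a BBB-probability table with planted high-permeability
compounds. Because the plants are known, every pipeline stage has an
exact expected answer.

Two emission modes mirror the asymmetry of real inputs: ``sets`` yields
precomputed up/down DEG sets per signature (like crowd-annotated disease
signatures), while ``expression`` yields replicated treatment/control
matrices with the planted DEGs as Gaussian mean shifts, exercising the
characteristic-direction and z-test stages too. All randomness flows from
a single mandatory seed; the same config reproduces byte-identical files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io
from .data_io import ExpressionExperiment, GeneSet, GeneSetLibrary
from .signatures import DiseaseSignature, Signature

MOA_PLANTED = "planted_moa"


class ConfigError(ValueError):
    """The synthetic configuration is inconsistent or unidentifiable."""


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic screen.

    Defaults describe a desk-scale analog of a landmark-gene drug-signature
    library: 978 genes, 3v3 replicates, 5% DEGs per signature at a mean
    shift of 2 noise SDs, 300 drugs x 4 conditions with 5 planted reversers
    whose down-sets capture 30% of the disease up-genes against a 2%
    background overlap.
    """

    seed: int
    n_genes: int = 978
    n_control: int = 3
    n_treatment: int = 3
    deg_fraction: float = 0.05
    effect_size: float = 2.0
    noise: float = 1.0
    n_drugs: int = 300
    conditions_per_drug: int = 4
    n_planted_reversers: int = 5
    reversal_overlap: float = 0.3
    background_overlap: float = 0.02
    disease_shared_fraction: float = 0.5
    n_moa_terms: int = 10
    planted_moa_size: int | None = None  # None: exactly the planted reversers
    n_bbb_high: int = 10

    def __post_init__(self) -> None:
        fractions = {
            "deg_fraction": self.deg_fraction,
            "reversal_overlap": self.reversal_overlap,
            "background_overlap": self.background_overlap,
            "disease_shared_fraction": self.disease_shared_fraction,
        }
        for name, v in fractions.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        counts = {
            "n_genes": self.n_genes,
            "n_control": self.n_control,
            "n_treatment": self.n_treatment,
            "n_drugs": self.n_drugs,
            "conditions_per_drug": self.conditions_per_drug,
            "n_moa_terms": self.n_moa_terms,
            "n_bbb_high": self.n_bbb_high,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigError(f"{name}={v} must be positive")
        if self.n_planted_reversers < 0 or self.n_planted_reversers > self.n_drugs:
            raise ConfigError("n_planted_reversers outside 0..n_drugs")
        if self.noise < 0 or self.effect_size < 0:
            raise ConfigError("noise and effect_size must be non-negative")
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if int(self.deg_fraction * self.n_genes) < 1:
            raise ConfigError("deg_fraction * n_genes < 1: signatures would be empty")
        if self.n_planted_reversers > 0 and self.reversal_overlap <= self.background_overlap:
            raise ConfigError(
                "reversal_overlap must exceed background_overlap or the planted "
                "signal is not identifiable"
            )
        if self.planted_moa_size is None:
            self.planted_moa_size = self.n_planted_reversers
        if self.planted_moa_size < self.n_planted_reversers:
            warnings.warn(
                "planted_moa_size < n_planted_reversers: the planted MOA cannot "
                "cover every reverser",
                stacklevel=2,
            )

    @property
    def deg_size(self) -> int:
        return int(round(self.deg_fraction * self.n_genes))

    @classmethod
    def from_file(cls, path: str | Path, seed: int | None = None) -> "SyntheticConfig":
        """Load a config from YAML or JSON; an explicit seed overrides the file."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if seed is not None:
            raw["seed"] = seed
        return cls(**raw)


@dataclass
class GroundTruth:
    """What was planted: the key for grading every stage of the screen."""

    disease_up: dict[str, list[str]]
    disease_down: dict[str, list[str]]
    planted_reversers: list[str]
    planted_signatures: dict[str, list[str]]  # reverser drug -> its signature ids
    planted_moa_drugs: list[str]
    bbb_high: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    mode: str
    gene_ids: list[str]
    disease_signatures: list[DiseaseSignature]
    signatures: list[Signature] | None
    experiments: dict[str, ExpressionExperiment] | None
    metadata: pd.DataFrame
    moa_table: pd.DataFrame
    bbb_table: pd.DataFrame
    truth: GroundTruth


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _drug_ids(n: int) -> list[str]:
    return [f"DRUG{i:04d}" for i in range(n)]


def generate_disease_signatures(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[DiseaseSignature], dict[str, dict[str, list[str]]]]:
    """Two disease signatures sharing ``disease_shared_fraction`` of up-genes.

    Each up/down set has ``deg_fraction * n_genes`` members; down-sets are
    disjoint from both up-sets.
    """
    genes = _gene_ids(config.n_genes)
    m = config.deg_size
    n_shared = int(round(config.disease_shared_fraction * m))
    pool = rng.permutation(config.n_genes)
    # carve non-overlapping index blocks: shared, unique1, unique2, down1, down2
    need = n_shared + 2 * (m - n_shared) + 2 * m
    if need > config.n_genes:
        raise ConfigError("gene universe too small for the requested DEG sizes")
    it = iter(pool)
    take = lambda k: [genes[next(it)] for _ in range(k)]
    shared = take(n_shared)
    up1 = shared + take(m - n_shared)
    up2 = shared + take(m - n_shared)
    down1 = take(m)
    down2 = take(m)
    universe = frozenset(genes)
    sigs = [
        DiseaseSignature("disease_sig1", frozenset(up1), frozenset(down1), universe),
        DiseaseSignature("disease_sig2", frozenset(up2), frozenset(down2), universe),
    ]
    truth = {
        "up": {"disease_sig1": sorted(up1), "disease_sig2": sorted(up2)},
        "down": {"disease_sig1": sorted(down1), "disease_sig2": sorted(down2)},
    }
    return sigs, truth


def _plant_down_set(
    rng: np.random.Generator,
    genes: list[str],
    disease_up_union: list[str],
    non_disease: list[str],
    overlap_fraction: float,
    size: int,
) -> list[str]:
    """A drug down-set drawing ``overlap_fraction`` of the disease up-union."""
    k_ov = int(round(overlap_fraction * len(disease_up_union)))
    k_ov = min(k_ov, size)
    picked = list(rng.choice(disease_up_union, size=k_ov, replace=False)) if k_ov else []
    rest = list(rng.choice(non_disease, size=size - k_ov, replace=False))
    return picked + rest


def generate_drug_library(
    config: SyntheticConfig,
    disease_signatures: list[DiseaseSignature],
    rng: np.random.Generator,
    mode: str = "sets",
) -> tuple[
    list[Signature] | None,
    dict[str, ExpressionExperiment] | None,
    pd.DataFrame,
    dict[str, object],
]:
    """Per drug x condition, a precomputed Signature or a replicate experiment.

    A planted reverser carries the elevated disease-up overlap in every one
    of its conditions — reversal is a property of the compound, and
    condition-to-condition variability enters through the expression noise,
    not by switching the mechanism off. Each condition's overlapping genes
    are drawn independently, so conditions still differ and the
    max-over-conditions rule has work to do. Background drug-condition
    down-sets overlap the disease up-union at ``background_overlap``. In
    expression mode the chosen up/down sets become mean shifts of
    ``effect_size * noise`` on the treatment replicates.
    """
    if mode not in ("sets", "expression"):
        raise ValueError(f"unknown mode {mode!r}")
    genes = _gene_ids(config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    up_union = sorted(set().union(*(d.up_set for d in disease_signatures)))
    non_disease = sorted(set(genes) - set(up_union))
    drugs = _drug_ids(config.n_drugs)
    reversers = sorted(
        str(d) for d in rng.choice(drugs, size=config.n_planted_reversers, replace=False)
    )
    m = config.deg_size

    metadata_rows = []
    signatures: list[Signature] = []
    experiments: dict[str, ExpressionExperiment] = {}
    planted_signatures: dict[str, list[str]] = {}
    reverser_set = set(reversers)
    cell_lines = ["CL1", "CL2"]
    doses = ["1uM", "10uM"]
    times = ["6h", "24h"]

    for drug in drugs:
        planted = drug in reverser_set
        for c in range(config.conditions_per_drug):
            sig_id = f"{drug}_c{c}"
            overlap = config.reversal_overlap if planted else config.background_overlap
            if planted:
                planted_signatures.setdefault(drug, []).append(sig_id)
            down = _plant_down_set(rng, genes, up_union, non_disease, overlap, m)
            up_pool = sorted(set(genes) - set(down))
            up = list(rng.choice(up_pool, size=m, replace=False))
            metadata_rows.append(
                {
                    "signature_id": sig_id,
                    "drug_id": drug,
                    "cell_line": cell_lines[c % len(cell_lines)],
                    "dose": doses[(c // len(cell_lines)) % len(doses)],
                    "time": times[c % len(times)],
                }
            )
            if mode == "sets":
                signatures.append(
                    Signature(
                        signature_id=sig_id,
                        drug_id=drug,
                        cell_line=metadata_rows[-1]["cell_line"],
                        dose=metadata_rows[-1]["dose"],
                        time=metadata_rows[-1]["time"],
                        up_set=frozenset(up),
                        down_set=frozenset(down),
                        gene_universe=tuple(genes),
                    )
                )
            else:
                n_c, n_t = config.n_control, config.n_treatment
                values = rng.normal(0.0, config.noise, size=(config.n_genes, n_c + n_t))
                shift = config.effect_size * config.noise
                up_idx = [gene_index[g] for g in up]
                down_idx = [gene_index[g] for g in down]
                values[up_idx, n_c:] += shift
                values[down_idx, n_c:] -= shift
                sample_ids = [f"{sig_id}_CTL{i}" for i in range(n_c)] + [
                    f"{sig_id}_TRT{i}" for i in range(n_t)
                ]
                classes = [data_io.CONTROL] * n_c + [data_io.TREATMENT] * n_t
                experiments[sig_id] = ExpressionExperiment(
                    genes, sample_ids, values, classes
                )

    metadata = pd.DataFrame(metadata_rows, columns=data_io.METADATA_COLUMNS)
    truth = {"reversers": reversers, "planted_signatures": planted_signatures}
    if mode == "sets":
        return signatures, None, metadata, truth
    return None, experiments, metadata, truth


def generate_annotations(
    config: SyntheticConfig,
    drugs: list[str],
    reversers: list[str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """MOA labels with one planted enriched class, and BBB scores.

    The planted MOA covers every reverser plus random fill to
    ``planted_moa_size`` (by default no fill: the planted class is exactly
    the reversers); remaining drugs spread uniformly over the other terms.
    BBB probabilities partition the [-1, 1] range: planted
    high-permeability compounds (the reversers plus random fill to
    ``n_bbb_high``) score uniformly in [0.8, 1.0], all others uniformly in
    [-1, 0.8), so planted-high status is recoverable from the scores.
    """
    others = [d for d in drugs if d not in set(reversers)]
    n_fill = max(0, min(config.planted_moa_size, len(drugs)) - len(reversers))
    moa_fill = [str(d) for d in rng.choice(others, size=n_fill, replace=False)]
    planted_moa_drugs = sorted(set(reversers) | set(moa_fill))
    moa_terms = [f"moa_{i:02d}" for i in range(config.n_moa_terms)]
    rows = []
    for d in drugs:
        if d in set(planted_moa_drugs):
            term = MOA_PLANTED
        else:
            term = moa_terms[int(rng.integers(config.n_moa_terms))]
        rows.append({"drug_id": d, "moa": term})
    moa_table = pd.DataFrame(rows, columns=["drug_id", "moa"])

    n_bbb_fill = max(0, min(config.n_bbb_high, len(drugs)) - len(reversers))
    bbb_fill = [
        str(d)
        for d in rng.choice(
            [d for d in others if d not in set(moa_fill)] or others,
            size=n_bbb_fill,
            replace=False,
        )
    ]
    bbb_high = sorted(set(reversers) | set(bbb_fill))
    bbb_scores = rng.uniform(-1.0, 0.8, size=len(drugs))
    bbb_table = pd.DataFrame({"compound_id": drugs, "bbb_probability": bbb_scores})
    high_mask = bbb_table["compound_id"].isin(bbb_high)
    bbb_table.loc[high_mask, "bbb_probability"] = rng.uniform(
        0.8, 1.0, size=int(high_mask.sum())
    )
    truth = {"planted_moa_drugs": planted_moa_drugs, "bbb_high": bbb_high}
    return moa_table, bbb_table, truth


def generate(config: SyntheticConfig, mode: str = "sets") -> SyntheticDataset:
    """Generate the full synthetic screen input from one seeded config."""
    rng = np.random.default_rng(config.seed)
    disease, dis_truth = generate_disease_signatures(config, rng)
    signatures, experiments, metadata, lib_truth = generate_drug_library(
        config, disease, rng, mode=mode
    )
    drugs = _drug_ids(config.n_drugs)
    moa_table, bbb_table, ann_truth = generate_annotations(
        config, drugs, lib_truth["reversers"], rng
    )
    truth = GroundTruth(
        disease_up=dis_truth["up"],
        disease_down=dis_truth["down"],
        planted_reversers=list(lib_truth["reversers"]),
        planted_signatures=dict(lib_truth["planted_signatures"]),
        planted_moa_drugs=ann_truth["planted_moa_drugs"],
        bbb_high=ann_truth["bbb_high"],
    )
    return SyntheticDataset(
        config=config,
        mode=mode,
        gene_ids=_gene_ids(config.n_genes),
        disease_signatures=disease,
        signatures=signatures,
        experiments=experiments,
        metadata=metadata,
        moa_table=moa_table,
        bbb_table=bbb_table,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit the dataset as the pipeline's file-based inputs.

    Writes disease up/down GMTs, the library (up/down GMT pair in sets
    mode, one GCT + class sidecar per signature in expression mode), the
    metadata TSV, MOA and BBB TSVs, and the ground-truth JSON. Emission is
    deterministic: the same config yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    up_entries = [
        GeneSet(d.name, "disease", sorted(d.up_set))
        for d in dataset.disease_signatures
    ]
    down_entries = [
        GeneSet(d.name, "disease", sorted(d.down_set))
        for d in dataset.disease_signatures
        if d.down_set
    ]
    paths["disease_up"] = outdir / "disease_up.gmt"
    data_io.write_gmt(GeneSetLibrary(up_entries), paths["disease_up"])
    paths["disease_down"] = outdir / "disease_down.gmt"
    data_io.write_gmt(GeneSetLibrary(down_entries), paths["disease_down"])

    paths["metadata"] = outdir / "library_metadata.tsv"
    data_io.write_metadata_table(dataset.metadata, paths["metadata"])

    if dataset.mode == "sets":
        assert dataset.signatures is not None
        from .signatures import library_to_gmt_pair

        up_lib, down_lib = library_to_gmt_pair(dataset.signatures)
        paths["library_up"] = outdir / "library_up.gmt"
        data_io.write_gmt(up_lib, paths["library_up"])
        paths["library_down"] = outdir / "library_down.gmt"
        data_io.write_gmt(down_lib, paths["library_down"])
    else:
        assert dataset.experiments is not None
        exp_dir = outdir / "experiments"
        exp_dir.mkdir(exist_ok=True)
        for sig_id in sorted(dataset.experiments):
            exp = dataset.experiments[sig_id]
            data_io.write_gct(exp, exp_dir / f"{sig_id}.gct")
            data_io.write_sample_classes(
                dict(zip(exp.sample_ids, exp.sample_class)),
                exp_dir / f"{sig_id}.classes.tsv",
            )
        paths["experiments_dir"] = exp_dir

    paths["moa"] = outdir / "moa.tsv"
    dataset.moa_table.to_csv(paths["moa"], sep="\t", index=False)
    paths["bbb"] = outdir / "bbb.tsv"
    dataset.bbb_table.to_csv(paths["bbb"], sep="\t", index=False)
    paths["truth"] = outdir / "ground_truth.json"
    dataset.truth.to_json(paths["truth"])
    return paths
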