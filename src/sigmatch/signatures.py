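"""Characteristic-direction signatures and z-test DEG calling.

The characteristic direction is a regularized linear-discriminant
direction separating treatment from control samples in gene space:

    b  ∝  Σ_shrunk⁻¹ (μ_treatment − μ_control),
    Σ_shrunk = (1 − γ)·Σ̂_pooled + γ·ν·I,   ν = trace(Σ̂_pooled) / p,

returned with unit Euclidean norm and oriented so that
b · (μ_treatment − μ_control) ≥ 0, i.e. a positive coefficient means the
gene is higher under treatment. With more genes than samples the pooled
covariance is rank-deficient; the inverse is applied exactly through the
sample-spanned subspace (Woodbury identity on the SVD of the within-class
centered data), never by forming a p × p matrix.

Up/down differentially expressed gene (DEG) sets are then called by a
z-test on the standardized coefficients at a two-sided significance
threshold (default p < 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import (
    CONTROL,
    TREATMENT,
    ExpressionExperiment,
    GeneSet,
    GeneSetLibrary,
    ValidationError,
)

DEFAULT_GAMMA = 0.5
DEFAULT_ALPHA = 0.01

_SVD_RTOL = 1e-12


class DegenerateSignalError(ValueError):
    """No direction can be estimated (zero mean difference or zero spread)."""


class NumericalError(ValueError):
    """The linear system is singular under the requested regularization."""


@dataclass
class DiseaseSignature:
    """Named up/down gene sets over a stated gene universe (set-based input)."""

    name: str
    up_set: frozenset[str]
    down_set: frozenset[str]
    gene_universe: frozenset[str]

    def __post_init__(self) -> None:
        self.up_set = frozenset(self.up_set)
        self.down_set = frozenset(self.down_set)
        self.gene_universe = frozenset(self.gene_universe)
        if self.up_set & self.down_set:
            raise ValidationError(f"{self.name}: up and down sets overlap")
        if not self.up_set <= self.gene_universe or not self.down_set <= self.gene_universe:
            raise ValidationError(f"{self.name}: DEG sets outside gene universe")


@dataclass
class Signature:
    """One perturbation signature: coefficients plus derived up/down DEG sets."""

    signature_id: str
    drug_id: str
    cell_line: str
    dose: str
    time: str
    up_set: frozenset[str]
    down_set: frozenset[str]
    gene_universe: tuple[str, ...]
    coefficients: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.up_set = frozenset(self.up_set)
        self.down_set = frozenset(self.down_set)
        self.gene_universe = tuple(self.gene_universe)
        if self.up_set & self.down_set:
            raise ValidationError(f"{self.signature_id}: up and down sets overlap")
        universe = set(self.gene_universe)
        if not self.up_set <= universe or not self.down_set <= universe:
            raise ValidationError(f"{self.signature_id}: DEG sets outside gene universe")
        if self.coefficients is not None:
            b = np.asarray(self.coefficients, dtype=float)
            if b.shape != (len(self.gene_universe),):
                raise ValidationError(f"{self.signature_id}: coefficient length mismatch")
            if abs(np.linalg.norm(b) - 1.0) > 1e-9:
                raise ValidationError(f"{self.signature_id}: coefficients not unit-norm")
            idx = {g: i for i, g in enumerate(self.gene_universe)}
            if any(b[idx[g]] <= 0 for g in self.up_set) or any(
                b[idx[g]] >= 0 for g in self.down_set
            ):
                raise ValidationError(
                    f"{self.signature_id}: DEG sets inconsistent with coefficient signs"
                )
            self.coefficients = b


def characteristic_direction(
    experiment: ExpressionExperiment, gamma: float = DEFAULT_GAMMA
) -> np.ndarray:
    """Compute the unit characteristic-direction coefficient vector.

    Parameters
    ----------
    experiment
        Replicated two-class experiment (>=1 control, >=1 treatment).
    gamma
        Covariance shrinkage toward the scaled identity, in [0, 1].
        gamma=1 reduces to the normalized mean difference; gamma=0 requires
        the pooled covariance to be full rank (more samples than genes).
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    X = experiment.values  # genes x samples
    ctrl = X[:, experiment.class_mask(CONTROL)]
    trt = X[:, experiment.class_mask(TREATMENT)]
    n = ctrl.shape[1] + trt.shape[1]
    if n < 2:
        raise ValidationError("need at least 2 samples")
    p = X.shape[0]

    d = trt.mean(axis=1) - ctrl.mean(axis=1)
    if not np.any(d):
        raise DegenerateSignalError("treatment and control means are identical")

    # within-class centered data, stacked: rows are samples, columns genes
    E = np.vstack([(ctrl - ctrl.mean(axis=1, keepdims=True)).T,
                   (trt - trt.mean(axis=1, keepdims=True)).T])
    dof = n - 2
    # thin SVD over the sample-spanned subspace; s holds singular values of E
    if dof > 0 and np.any(E):
        _, s, Vt = np.linalg.svd(E, full_matrices=False)
        keep = s > s[0] * _SVD_RTOL
        s, Vt = s[keep], Vt[keep]
        eig = s**2 / dof  # nonzero eigenvalues of the pooled covariance
    else:
        eig = np.empty(0)
        Vt = np.empty((0, p))
    nu = eig.sum() / p
    if nu <= 0.0:
        # no within-class variation: Sigma_shrunk = gamma*nu*I is scalar and
        # its scale cancels in the direction, so any positive nu serves
        nu = 1.0

    if gamma == 0.0:
        if len(eig) < p:
            raise NumericalError(
                "pooled covariance is singular with samples <= genes; use gamma > 0"
            )
        b = Vt.T @ ((Vt @ d) / eig)
    else:
        a = gamma * nu
        lam = (1.0 - gamma) * eig
        # Woodbury: (aI + V diag(lam) V^T)^-1 d
        b = (d - Vt.T @ ((lam / (lam + a)) * (Vt @ d))) / a

    if b @ d < 0:
        b = -b
    return b / np.linalg.norm(b)


def call_degs(
    coefficients: np.ndarray,
    gene_ids: list[str] | tuple[str, ...],
    alpha: float = DEFAULT_ALPHA,
) -> tuple[frozenset[str], frozenset[str]]:
    """Call up/down DEG sets from coefficients by a two-sided z-test.

    Coefficients are standardized over genes, z_g = (b_g − mean b)/sd(b),
    and gene g enters the up (down) set iff 2(1 − Φ(|z_g|)) < alpha and
    b_g > 0 (< 0).
    """
    b = np.asarray(coefficients, dtype=float)
    if b.ndim != 1 or len(b) != len(gene_ids):
        raise ValueError("coefficients and gene_ids must align")
    if len(b) < 3:
        raise ValueError("need at least 3 genes for the z-test")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    sd = b.std(ddof=1)
    if sd == 0.0:
        raise DegenerateSignalError("coefficients have zero spread")
    z = (b - b.mean()) / sd
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    sig = pvals < alpha
    gene_ids = list(gene_ids)
    up = frozenset(g for g, s, v in zip(gene_ids, sig, b) if s and v > 0)
    down = frozenset(g for g, s, v in zip(gene_ids, sig, b) if s and v < 0)
    return up, down


def build_signature_library(
    experiments: dict[str, ExpressionExperiment],
    metadata: pd.DataFrame,
    gamma: float = DEFAULT_GAMMA,
    alpha: float = DEFAULT_ALPHA,
) -> list[Signature]:
    """Build one Signature per experiment, ordered by signature_id.

    ``metadata`` must have exactly one row per experiment key (columns
    signature_id, drug_id, cell_line, dose, time).
    """
    meta_ids = set(metadata["signature_id"])
    exp_ids = set(experiments)
    if meta_ids != exp_ids:
        missing_meta = sorted(exp_ids - meta_ids)
        missing_exp = sorted(meta_ids - exp_ids)
        raise ValidationError(
            f"metadata/experiment mismatch: no metadata for {missing_meta[:5]}, "
            f"no experiment for {missing_exp[:5]}"
        )
    rows = metadata.set_index("signature_id")
    out: list[Signature] = []
    for sig_id in sorted(experiments):
        exp = experiments[sig_id]
        b = characteristic_direction(exp, gamma=gamma)
        up, down = call_degs(b, exp.gene_ids, alpha=alpha)
        r = rows.loc[sig_id]
        out.append(
            Signature(
                signature_id=sig_id,
                drug_id=str(r["drug_id"]),
                cell_line=str(r["cell_line"]),
                dose=str(r["dose"]),
                time=str(r["time"]),
                up_set=up,
                down_set=down,
                gene_universe=tuple(exp.gene_ids),
                coefficients=b,
            )
        )
    return out


def library_from_gmt_pair(
    up_library: GeneSetLibrary,
    down_library: GeneSetLibrary,
    metadata: pd.DataFrame,
    gene_universe: list[str] | None = None,
) -> list[Signature]:
    """Assemble precomputed signatures from an up/down GMT pair.

    This is the set-based bypass for libraries supplied without expression
    matrices; set names are signature ids and a signature absent from one
    of the two files gets an empty set on that side. If ``gene_universe``
    is None it defaults to the union of all members.
    """
    up = up_library.as_dict()
    down = down_library.as_dict()
    sig_ids = sorted(set(up) | set(down))
    meta_ids = set(metadata["signature_id"])
    missing = [s for s in sig_ids if s not in meta_ids]
    if missing:
        raise ValidationError(f"signatures without metadata: {missing[:5]}")
    if gene_universe is None:
        universe: set[str] = set()
        for members in (*up.values(), *down.values()):
            universe |= members
        gene_universe = sorted(universe)
    rows = metadata.set_index("signature_id")
    out: list[Signature] = []
    for sig_id in sig_ids:
        r = rows.loc[sig_id]
        out.append(
            Signature(
                signature_id=sig_id,
                drug_id=str(r["drug_id"]),
                cell_line=str(r["cell_line"]),
                dose=str(r["dose"]),
                time=str(r["time"]),
                up_set=frozenset(up.get(sig_id, ())),
                down_set=frozenset(down.get(sig_id, ())),
                gene_universe=tuple(gene_universe),
            )
        )
    return out


def library_to_gmt_pair(
    library: list[Signature],
) -> tuple[GeneSetLibrary, GeneSetLibrary]:
    """Serialize a signature library as (up, down) GMT libraries.

    Signatures with an empty set on one side are omitted from that file
    (GMT cannot represent an empty set).
    """
    ups = [
        GeneSet(s.signature_id, s.drug_id, sorted(s.up_set))
        for s in library
        if s.up_set
    ]
    downs = [
        GeneSet(s.signature_id, s.drug_id, sorted(s.down_set))
        for s in library
        if s.down_set
    ]
    return GeneSetLibrary(ups), GeneSetLibrary(downs)


def disease_signatures_from_gmt(
    up_library: GeneSetLibrary,
    down_library: GeneSetLibrary | None = None,
    gene_universe: list[str] | None = None,
) -> list[DiseaseSignature]:
    """Build disease signatures from an up-set GMT and optional down-set GMT."""
    down = down_library.as_dict() if down_library is not None else {}
    if gene_universe is None:
        universe: set[str] = set()
        for members in up_library.as_dict().values():
            universe |= members
        for members in down.values():
            universe |= members
        gene_universe = sorted(universe)
    out = []
    for entry in up_library:
        out.append(
            DiseaseSignature(
                name=entry.name,
                up_set=frozenset(entry.members),
                down_set=frozenset(down.get(entry.name, ())),
                gene_universe=frozenset(gene_universe),
            )
        )
    return out
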