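"""Expression representatives: CPM profiles, module eigengenes, module hubs.

A correlation strategy pairs a *gene representative* with a *miRNA
representative*.  Three kinds exist on each side:

``cpm_feature``
    the feature's own CPM profile;
``eigengene``
    the first principal component of the module's per-feature standardized
    expression (WGCNA convention), sign-oriented toward the mean member
    profile and scaled to unit Euclidean norm;
``hub``
    the CPM profile of the module member with maximal \\|kME\\|, where kME is
    the Pearson correlation of the member's profile with the eigengene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from cormit.data_io import UNASSIGNED_MODULE, ExpressionMatrix, ModuleAssignment

logger = logging.getLogger("cormit")

REP_KINDS = ("cpm_feature", "eigengene", "hub")


@dataclass
class RepresentativeProfile:
    """One representative expression vector over the shared sample order."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    source_kind: str  # cpm_feature | eigengene | hub
    origin: str       # feature_id (cpm_feature/hub) or module_id

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.sample_ids):
            raise ValueError("profile length must equal number of samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")


#: feature_id -> RepresentativeProfile; members of one module share the
#: same profile object under the eigengene/hub kinds
RepresentativeMap = dict[str, RepresentativeProfile]


def cpm_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million normalization: value / column sum * 1e6."""
    if counts.normalized:
        raise ValueError("matrix is already normalized")
    colsums = counts.values.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(
            f"zero-sum sample column(s): {sorted(map(str, zero.index))}"
        )
    cpm = counts.values.div(colsums, axis=1) * 1e6
    return ExpressionMatrix(values=cpm, kind=counts.kind, normalized=True)


def _standardized_members(
    expr: ExpressionMatrix, assignment: ModuleAssignment, module_id: str
) -> tuple[list[str], np.ndarray]:
    """Member ids present in expr and their row-standardized profiles.

    Standardization is per feature across samples with population sd
    (divisor n); constant members are dropped with a warning.
    """
    if module_id == UNASSIGNED_MODULE:
        raise ValueError("the unassigned module has no representative profile")
    members = [m for m in assignment.members(module_id)
               if m in expr.values.index]
    if not members:
        raise ValueError(f"module {module_id!r} has no members in the matrix")
    mat = expr.values.loc[members].to_numpy(dtype=float)
    sd = mat.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [m for m, k in zip(members, keep) if not k]
        logger.warning(
            "module %s: dropped %d constant member(s) from PCA: %s",
            module_id, len(dropped), ", ".join(dropped[:5]),
        )
    members = [m for m, k in zip(members, keep) if k]
    if not members:
        raise ValueError(
            f"module {module_id!r}: all members constant across samples"
        )
    mat = mat[keep]
    z = (mat - mat.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return members, z


def module_eigengene(
    expr: ExpressionMatrix, assignment: ModuleAssignment, module_id: str
) -> RepresentativeProfile:
    """First PC of the standardized module expression, unit norm.

    The sign is oriented so the eigengene correlates non-negatively with the
    mean standardized member profile; exact zero correlation (possible only
    in contrived balanced modules) is resolved by making the first non-zero
    entry positive, keeping the output deterministic.
    """
    _members, z = _standardized_members(expr, assignment, module_id)
    # right singular vectors live in sample space; the first one is the PC
    _u, _s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = z.mean(axis=0)
    cov = float(np.dot(eig - eig.mean(), mean_profile - mean_profile.mean()))
    if cov < 0:
        eig = -eig
    elif cov == 0:
        nz = np.nonzero(eig)[0]
        if len(nz) and eig[nz[0]] < 0:
            eig = -eig
    return RepresentativeProfile(
        values=eig,
        sample_ids=tuple(expr.sample_ids),
        source_kind="eigengene",
        origin=module_id,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return np.nan
    return float(np.dot(xc, yc) / denom)


def module_hub_profile(
    expr: ExpressionMatrix, assignment: ModuleAssignment, module_id: str
) -> RepresentativeProfile:
    """CPM profile of the max-|kME| member (ties: smallest feature id)."""
    eig = module_eigengene(expr, assignment, module_id)
    members = [m for m in assignment.members(module_id)
               if m in expr.values.index]
    best_id, best_kme = None, -np.inf
    for m in members:  # sorted by id -> first max wins ties
        r = _pearson(expr.values.loc[m].to_numpy(dtype=float), eig.values)
        kme = abs(r) if np.isfinite(r) else -np.inf
        if kme > best_kme:
            best_id, best_kme = m, kme
    if best_id is None:
        raise ValueError(f"module {module_id!r}: no member with defined kME")
    return RepresentativeProfile(
        values=expr.values.loc[best_id].to_numpy(dtype=float),
        sample_ids=tuple(expr.sample_ids),
        source_kind="hub",
        origin=best_id,
    )


def build_representatives(
    expr: ExpressionMatrix,
    assignment: ModuleAssignment,
    rep_kind: str,
) -> RepresentativeMap:
    """Map every eligible feature to its representative profile.

    For ``cpm_feature`` every feature maps to its own row.  For the module
    kinds, every member of every real (non-"0") module maps to the shared
    module representative; modules whose representative cannot be computed
    are skipped with a warning and their members left out of the map.
    """
    if rep_kind not in REP_KINDS:
        raise ValueError(f"unknown representative kind {rep_kind!r}")
    samples = tuple(expr.sample_ids)
    out: RepresentativeMap = {}
    if rep_kind == "cpm_feature":
        for fid in expr.feature_ids:
            out[fid] = RepresentativeProfile(
                values=expr.values.loc[fid].to_numpy(dtype=float),
                sample_ids=samples,
                source_kind="cpm_feature",
                origin=fid,
            )
        return out
    builder = module_eigengene if rep_kind == "eigengene" else module_hub_profile
    for module_id in assignment.module_ids():
        members = [m for m in assignment.members(module_id)
                   if m in expr.values.index]
        if not members:
            continue
        try:
            profile = builder(expr, assignment, module_id)
        except ValueError as exc:
            logger.warning("skipping module %s: %s", module_id, exc)
            continue
        # module-kind profiles keep the module as origin so pair
        # correlations can be computed once per module and broadcast
        if rep_kind == "hub":
            profile = RepresentativeProfile(
                values=profile.values, sample_ids=profile.sample_ids,
                source_kind="hub", origin=module_id,
            )
        for m in members:
            out[m] = profile
    return out
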