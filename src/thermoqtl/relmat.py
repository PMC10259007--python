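"""Pedigree (A) and genomic (G) relationship matrices.

A is built by the tabular method (diagonal = 1 + inbreeding coefficient);
G follows VanRaden's first method with observed allele frequencies, and is
blended with A (default weight 0.95 on G) to guarantee invertibility for
the mixed-model solvers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GenotypeMatrix, Pedigree


@dataclass
class RelationshipMatrix:
    ids: list[str]
    values: np.ndarray  # (n, n) symmetric
    kind: str  # pedigree | genomic | blended
    blend_weight: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        self.values = 0.5 * (v + v.T)

    def subset(self, ids: list[str]) -> "RelationshipMatrix":
        pos = {a: i for i, a in enumerate(self.ids)}
        idx = np.array([pos[str(a)] for a in ids], dtype=np.int64)
        return RelationshipMatrix(
            ids=[self.ids[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
            kind=self.kind,
            blend_weight=self.blend_weight,
        )

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values).min())


def a_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular recursion.

    Requires the pedigree sorted parents-before-offspring (enforced by the
    :class:`Pedigree` container, which also rejects ancestry cycles).
    For animal i with parents s, d:  A[i, j] = (A[s, j] + A[d, j]) / 2 for
    j < i and A[i, i] = 1 + A[s, d] / 2.
    """
    n = pedigree.n
    parents = pedigree.parent_indices()
    a = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        s, d = parents[i]
        if s < 0 and d < 0:
            a[i, i] = 1.0
            continue
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * a[s, :i]
        if d >= 0:
            row += 0.5 * a[d, :i]
        a[i, :i] = row
        a[:i, i] = row
        inbreeding = 0.5 * a[s, d] if (s >= 0 and d >= 0) else 0.0
        a[i, i] = 1.0 + inbreeding
    return RelationshipMatrix(ids=pedigree.ids, values=a, kind="pedigree")


def g_matrix(
    genotypes: GenotypeMatrix,
    blend_weight: float = 0.95,
    a: RelationshipMatrix | None = None,
) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Columns of the dosage matrix are centred by twice the observed allele
    frequency; cross-products are divided by 2*sum(p(1-p)).  Missing calls
    are mean-imputed per SNP beforehand.  With ``blend_weight`` w < 1 the
    result is w*G + (1-w)*A over the same individuals (A defaults to the
    identity when no pedigree matrix is supplied).
    """
    if not (0.0 < blend_weight <= 1.0):
        raise ValueError("blend_weight must lie in (0, 1]")
    z = genotypes.mean_imputed()
    p = z.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if poly.sum() < 2:
        raise ValueError("need at least two polymorphic SNPs for G")
    zc = z[:, poly] - 2.0 * p[poly]
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    g = (zc @ zc.T) / denom
    kind = "genomic"
    if blend_weight < 1.0:
        if a is None:
            a_vals = np.eye(genotypes.n_individuals)
        else:
            a_vals = a.subset(genotypes.ids).values
        g = blend_weight * g + (1.0 - blend_weight) * a_vals
        kind = "blended"
    return RelationshipMatrix(
        ids=list(genotypes.ids), values=g, kind=kind,
        blend_weight=blend_weight if blend_weight < 1.0 else None,
    )
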