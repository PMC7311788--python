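"""Per-dimension PCAs and the second-stage "PCA of PCAs" niche space.

Stage 1 runs one PCA per niche dimension (leaf economy, mechanical support,
reproductive phenology) on the log10-transformed, standardized trait block
and keeps each dimension's first two species-score columns.  Stage 2 runs a
PCA on those six standardized gradient columns; its PC1/PC2 scores are the
species positions in the continuous niche space.

Both stages work on the correlation scale (columns centered and scaled to
unit sample variance): the traits are on incommensurate units, and the
published variance bookkeeping of the second stage (eigenvalues summing to
the six inputs) only holds for standardized inputs.  Axis orientation is
made deterministic by flipping each eigenvector so its largest-magnitude
loading is positive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .traits import DEFAULT_SCHEME, BIOMES, DimensionScheme, TraitTable

__all__ = [
    "OrdinationError",
    "PcaResult",
    "DimensionGradients",
    "NicheSpace",
    "SpaceSummary",
    "pca",
    "fix_sign",
    "dimension_pca",
    "pca_of_pcas",
    "niche_space",
    "summarize_space",
]

log = logging.getLogger(__name__)

#: Eigenvalues below this are numerical noise and are clamped to zero.
EIGENVALUE_FLOOR = 1e-10

#: Two |loadings| within this of the maximum tie for "dominant variable".
DOMINANT_TIE_TOL = 1e-6


class OrdinationError(ValueError):
    """Invalid ordination input (zero-variance column, misaligned index...)."""


@dataclass
class PcaResult:
    """Full eigendecomposition of one standardized (or centered) matrix.

    ``eigenvectors`` has one unit-length column per component; ``scores`` are
    the centered(-scaled) data projected on them.  ``eigenvalues`` are sorted
    descending and, for standardized input, sum to the number of variables.
    """

    variable_names: list[str]
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    eigenvectors: np.ndarray  # (p, p), columns are components
    scores: pd.DataFrame  # (n, p), columns PC1..PCp
    center: np.ndarray
    scale: np.ndarray | None
    standardized: bool

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def loadings(self, k: int = 2) -> pd.DataFrame:
        """Unit eigenvector loadings for the first ``k`` components."""
        k = min(k, self.n_components)
        return pd.DataFrame(
            self.eigenvectors[:, :k],
            index=self.variable_names,
            columns=[f"PC{i+1}" for i in range(k)],
        )

    def scaled_loadings(self, k: int = 2) -> pd.DataFrame:
        """Eigenvectors scaled by sqrt(eigenvalue) (vegan-style species scaling).

        Secondary reporting convention; entries can exceed 1 in magnitude.
        """
        k = min(k, self.n_components)
        return self.loadings(k) * np.sqrt(self.eigenvalues[:k])

    def dominant_variables(self, component: int) -> list[str]:
        """Variables carrying the largest |loading| on a 0-based component.

        Ties within :data:`DOMINANT_TIE_TOL` are all reported (e.g. height
        and diameter jointly read as "plant size").
        """
        mags = np.abs(self.eigenvectors[:, component])
        top = mags.max()
        return [n for n, m in zip(self.variable_names, mags) if top - m <= DOMINANT_TIE_TOL]


def pca(data: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """Principal component analysis via SVD of the centered(-scaled) matrix.

    Requires >=3 rows, >=2 columns and no missing cells.  With more columns
    than rows the trailing eigenvalues are zero and reported as such.  Sample
    statistics use ddof=1, so standardized eigenvalues sum to the column
    count exactly.  The returned axes are sign-canonicalized.
    """
    if data.isna().any().any():
        raise OrdinationError("missing values in PCA input")
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if n < 3:
        raise OrdinationError(f"PCA needs at least 3 rows, got {n}")
    if p < 2:
        raise OrdinationError(f"PCA needs at least 2 columns, got {p}")
    center = X.mean(axis=0)
    Xc = X - center
    scale = None
    if standardize:
        scale = X.std(axis=0, ddof=1)
        dead = [c for c, s in zip(data.columns, scale) if s == 0]
        if dead:
            raise OrdinationError(f"zero-variance column(s) {dead} cannot be standardized")
        Xc = Xc / scale
    # full_matrices so rank-deficient input still yields p orthonormal axes
    _, svals, vt = np.linalg.svd(Xc, full_matrices=True)
    eigenvalues = np.zeros(p)
    eigenvalues[: len(svals)] = svals**2 / (n - 1)
    eigenvalues[eigenvalues < EIGENVALUE_FLOOR] = 0.0
    if p > n:
        log.warning("PCA input has more columns (%d) than rows (%d); "
                    "trailing eigenvalues are zero", p, n)
    total = eigenvalues.sum()
    percent = eigenvalues / total * 100.0
    eigenvectors = vt.T  # (p, p)
    scores = pd.DataFrame(
        Xc @ eigenvectors, index=data.index, columns=[f"PC{i+1}" for i in range(p)]
    )
    result = PcaResult(
        variable_names=list(data.columns),
        eigenvalues=eigenvalues,
        percent_variance=percent,
        eigenvectors=eigenvectors,
        scores=scores,
        center=center,
        scale=scale,
        standardized=standardize,
    )
    return fix_sign(result)


def fix_sign(result: PcaResult) -> PcaResult:
    """Canonicalize eigenvector orientation (largest |loading| positive).

    PCA axes are defined up to sign; this makes reports reproducible.  Scores
    are flipped consistently so the decomposition is unchanged.  Idempotent.
    """
    vecs = result.eigenvectors.copy()
    scores = result.scores.copy()
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
            scores.iloc[:, j] = -scores.iloc[:, j]
    return replace(result, eigenvectors=vecs, scores=scores)


@dataclass
class DimensionGradients:
    """The six stage-1 gradient columns feeding the second PCA.

    ``scores`` columns are pc1.<dim>, pc2.<dim> for the three dimensions, on
    a shared species index; ``dominant`` maps each column to its major
    eigenvector annotation (the trait(s) with the largest |loading|).
    """

    scores: pd.DataFrame
    dominant: dict[str, str]

    def __post_init__(self) -> None:
        if self.scores.shape[1] != 6:
            raise OrdinationError(f"expected 6 gradient columns, got {self.scores.shape[1]}")


def dimension_pca(
    log_table: pd.DataFrame, scheme: DimensionScheme = DEFAULT_SCHEME
) -> tuple[dict[str, PcaResult], DimensionGradients]:
    """Stage-1 PCAs: one per niche dimension on the log10 trait table.

    Returns the per-dimension :class:`PcaResult` and the assembled
    six-column :class:`DimensionGradients` (PC1/PC2 species scores per
    dimension, annotated with their dominant traits).
    """
    results: dict[str, PcaResult] = {}
    cols: dict[str, pd.Series] = {}
    dominant: dict[str, str] = {}
    for dim in ("leaf_economy", "mechanical_support", "reproductive_phenology"):
        traits = scheme.traits_of(dim)
        if len(traits) < 2:
            raise OrdinationError(f"dimension {dim} has <2 traits")
        res = pca(log_table[traits], standardize=True)
        results[dim] = res
        for axis in (1, 2):
            name = f"pc{axis}.{dim}"
            cols[name] = res.scores[f"PC{axis}"]
            dominant[name] = "+".join(res.dominant_variables(axis - 1))
    gradients = DimensionGradients(scores=pd.DataFrame(cols), dominant=dominant)
    return results, gradients


@dataclass
class NicheSpace:
    """Species coordinates in the continuous niche ordination space.

    ``scores`` carries all second-stage components (PC1/PC2 are the niche
    plane); ``loadings`` are the six input gradients' unit loadings.
    """

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    loadings: pd.DataFrame
    biomes: tuple[str, ...]
    pca: PcaResult
    gradient_dominant: dict[str, str]

    @property
    def xy(self) -> pd.DataFrame:
        return self.scores[["PC1", "PC2"]]


def pca_of_pcas(gradients: DimensionGradients, biomes: tuple[str, ...] = ()) -> NicheSpace:
    """Stage 2: PCA on the six standardized gradient columns.

    Species with fewer rows than columns are allowed (a six-species biome
    yields trailing zero eigenvalues and a small-n warning).
    """
    scores = gradients.scores
    if scores.isna().any().any():
        offenders = scores.index[scores.isna().any(axis=1)].tolist()
        raise OrdinationError(f"gradient rows with missing scores: {offenders}")
    if scores.shape[0] <= scores.shape[1]:
        warnings.warn(
            f"niche space fitted on only {scores.shape[0]} species; "
            "trailing eigenvalues are zero and axes are fragile",
            stacklevel=2,
        )
    res = pca(scores, standardize=True)
    return NicheSpace(
        scores=res.scores,
        eigenvalues=res.eigenvalues,
        percent_variance=res.percent_variance,
        loadings=res.loadings(k=res.n_components),
        biomes=tuple(biomes),
        pca=res,
        gradient_dominant=dict(gradients.dominant),
    )


def niche_space(
    table: TraitTable, scheme: DimensionScheme = DEFAULT_SCHEME
) -> tuple[dict[str, PcaResult], NicheSpace]:
    """Full two-stage ordination of one trait table (one biome or pooled)."""
    from .traits import log10_transform

    logged = log10_transform(table)
    dim_results, gradients = dimension_pca(logged, scheme)
    seen = table.data.index.get_level_values(1)
    covered = tuple(b for b in BIOMES if b in set(seen))
    return dim_results, pca_of_pcas(gradients, biomes=covered)


@dataclass
class SpaceSummary:
    """Report tables for one niche space.

    ``niche`` mirrors the published niche-variation layout: eigenvalues and
    percent variance of PC1/PC2 plus each gradient's unit loading, a
    vegan-style scaled loading, and a dominance flag.  ``dimensions`` mirrors
    the per-dimension layout: percent variance and major eigenvector for the
    first two axes of each stage-1 PCA.
    """

    niche: pd.DataFrame
    dimensions: pd.DataFrame


def summarize_space(space: NicheSpace, dim_results: dict[str, PcaResult]) -> SpaceSummary:
    rows = []
    for grad in space.loadings.index:
        row = {"gradient": grad.replace("_", " "), "dominant_trait": space.gradient_dominant[grad]}
        for axis in (1, 2):
            pc = f"PC{axis}"
            load = space.loadings.loc[grad, pc]
            row[f"{pc.lower()}_loading"] = load
            row[f"{pc.lower()}_scaled"] = load * np.sqrt(space.eigenvalues[axis - 1])
            top = space.loadings[pc].abs().max()
            row[f"{pc.lower()}_dominant"] = bool(top - abs(load) <= DOMINANT_TIE_TOL)
        rows.append(row)
    niche = pd.DataFrame(rows).set_index("gradient")
    header = pd.DataFrame(
        {
            "pc1_loading": [space.eigenvalues[0], space.percent_variance[0]],
            "pc2_loading": [space.eigenvalues[1], space.percent_variance[1]],
        },
        index=["eigenvalue", "percent_variance"],
    )
    niche = pd.concat([header, niche])

    dim_rows = []
    for dim, res in dim_results.items():
        for axis in (1, 2):
            dim_rows.append(
                {
                    "dimension": dim.replace("_", " "),
                    "axis": f"PC{axis}",
                    "percent": res.percent_variance[axis - 1],
                    "major_eigenvector": "+".join(res.dominant_variables(axis - 1)),
                }
            )
    return SpaceSummary(niche=niche, dimensions=pd.DataFrame(dim_rows))
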