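"""Unsupervised stratification of serological signatures.

Hierarchical clustering (Ward's minimum-variance criterion on Euclidean
distances, both axes) of the individual fold-change matrix restricted to the
called biomarkers; sub-cohort signature comparison (re-running the penetrance
pipeline on a case subset against the unchanged controls); and
disease-association annotation against a pluggable target table (the
packaged Open Targets transcription by default).

Heatmap cells are raw individual fold changes — fold change is the quantity
the clustering is defined on — with an optional per-protein z-score toggle.
Ward linkage is deterministic, so repeated runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from skbio.tree import TreeNode

from .penetrance import PenetranceResult, score_penetrance
from .reference_data import disease_associations


class StratificationError(ValueError):
    pass


@dataclass
class ClusterResult:
    """Ward linkage trees and leaf orders for both axes of the FC matrix."""

    matrix: pd.DataFrame  # biomarkers x samples, individual FC
    sample_linkage: np.ndarray | None
    protein_linkage: np.ndarray | None
    sample_order: list[str]
    protein_order: list[str]

    def cut_samples(self, k: int) -> pd.Series:
        """Flat cluster labels from cutting the sample tree into k groups."""
        if self.sample_linkage is None:
            raise StratificationError("sample axis was not clustered")
        labels = fcluster(self.sample_linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.matrix.columns, name="cluster")


def _axis_linkage(data: np.ndarray, labels: list[str]):
    if len(labels) < 2:
        return None, list(labels)
    Z = linkage(data, method="ward", metric="euclidean")
    order = dendrogram(Z, no_plot=True)["leaves"]
    return Z, [labels[i] for i in order]


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a SciPy linkage matrix as a newick string."""
    tree = TreeNode.from_linkage_matrix(Z, labels)
    return str(tree).strip()


def cluster_heatmap(
    fc_matrix: pd.DataFrame,
    biomarkers: list[str] | None = None,
    image_path: str | Path | None = None,
    zscore_rows: bool = False,
) -> ClusterResult:
    """Ward/Euclidean clustering of the biomarker FC matrix, both axes.

    *fc_matrix* is proteins x samples; *biomarkers* restricts the rows.  An
    axis with fewer than two items is left unclustered (with a warning in the
    returned orders being the input order).  If *image_path* is given, a
    heatmap with dendrogram-ordered rows/columns is written there (PNG/SVG by
    extension).
    """
    M = fc_matrix.loc[biomarkers] if biomarkers is not None else fc_matrix
    if M.empty:
        raise StratificationError("empty fold-change matrix")
    plotted = M.sub(M.mean(axis=1), axis=0).div(M.std(axis=1).replace(0, 1), axis=0) if zscore_rows else M

    protein_linkage, protein_order = _axis_linkage(
        plotted.to_numpy(), list(M.index)
    )
    sample_linkage, sample_order = _axis_linkage(
        plotted.to_numpy().T, list(M.columns)
    )
    result = ClusterResult(
        matrix=M,
        sample_linkage=sample_linkage,
        protein_linkage=protein_linkage,
        sample_order=sample_order,
        protein_order=protein_order,
    )
    if image_path is not None:
        _write_heatmap(plotted, result, Path(image_path))
    return result


def _write_heatmap(plotted: pd.DataFrame, result: ClusterResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = plotted.loc[result.protein_order, result.sample_order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * ordered.shape[1] + 2), max(3, 0.25 * ordered.shape[0] + 1))
    )
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(ordered.shape[1]), ordered.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(ordered.shape[0]), ordered.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="individual fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class SignatureComparison:
    """Overlap partition of the full-cohort and sub-cohort signatures."""

    signature_full: set[str]
    signature_subcohort: set[str]
    overlap: set[str] = field(init=False)
    unique_to_subcohort: set[str] = field(init=False)
    unique_to_full: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.overlap = self.signature_full & self.signature_subcohort
        self.unique_to_subcohort = self.signature_subcohort - self.signature_full
        self.unique_to_full = self.signature_full - self.signature_subcohort


def subcohort_signature(
    H: pd.DataFrame,
    case_ids: list[str],
    control_ids: list[str],
    case_subset: list[str],
    **penetrance_kwargs,
) -> tuple[SignatureComparison, PenetranceResult, PenetranceResult]:
    """Re-run the penetrance pipeline on a case subset vs the same controls.

    Returns the signature overlap partition plus both full and sub-cohort
    penetrance results.
    """
    if not case_subset:
        raise StratificationError("case subset is empty")
    unknown = set(case_subset) - set(case_ids)
    if unknown:
        raise StratificationError(f"subset samples not among cases: {sorted(unknown)}")
    full = score_penetrance(H, case_ids, control_ids, **penetrance_kwargs)
    sub = score_penetrance(H, list(case_subset), control_ids, **penetrance_kwargs)
    return (
        SignatureComparison(
            signature_full=full.signature, signature_subcohort=sub.signature
        ),
        full,
        sub,
    )


def annotate_disease(
    biomarkers: list[str] | set[str],
    association_table: dict[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Label each biomarker with the diseases whose target sets contain it.

    Returns a table (protein, diseases, n_diseases); proteins absent from
    every target set get an empty label — these are the novel candidates.
    """
    table = association_table if association_table is not None else disease_associations()
    rows = []
    for protein in sorted(set(biomarkers)):
        diseases = sorted(d for d, targets in table.items() if protein in targets)
        rows.append(
            {"protein": protein, "diseases": ";".join(diseases), "n_diseases": len(diseases)}
        )
    return pd.DataFrame(rows, columns=["protein", "diseases", "n_diseases"])


def disease_summary(
    biomarkers: list[str] | set[str],
    association_table: dict[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Per-disease counts of associated biomarkers among *biomarkers*."""
    table = association_table if association_table is not None else disease_associations()
    marks = set(biomarkers)
    rows = [
        {
            "disease": disease,
            "n_targets": len(targets & marks),
            "targets": " ".join(sorted(targets & marks)),
        }
        for disease, targets in table.items()
    ]
    return pd.DataFrame(rows, columns=["disease", "n_targets", "targets"])


def read_association_tsv(path: str | Path) -> dict[str, frozenset[str]]:
    """Load a disease-association table (TSV: disease<TAB>space-separated targets)."""
    table: dict[str, frozenset[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        disease, _, targets = line.partition("\t")
        table[disease] = frozenset(targets.split())
    return table


def write_association_tsv(
    table: dict[str, frozenset[str]], path: str | Path
) -> Path:
    path = Path(path)
    lines = [f"{d}\t{' '.join(sorted(t))}" for d, t in table.items()]
    path.write_text("\n".join(lines) + "\n")
    return path
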