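"""Neighborhood visualization: local PCA of a term and its top-k neighbors.

The (k+1) selected vectors are projected onto their own first two principal
components — a local view of the neighborhood, not a projection of the full
vocabulary (a ``scope="global"`` switch fits the PCA on every vector
instead).  The original-space cosine rank survives the projection as marker
size (rank 1 = biggest circle), and relation types from an optional
knowledge base become marker symbols, so the plot shows both where PCA
places the neighbors and how far each actually is in the unreduced space.

Determinism: component signs are fixed by making each component's
largest-magnitude loading positive, so coordinates are reproducible
bit-for-bit.  A coordinates TSV is always available so nothing downstream
needs to parse images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .embeddings import EmbeddingMatrix, nearest_neighbors_of_term
from .kb import RelationKB

__all__ = ["ProjectedNeighborhood", "project_neighborhood", "plot_neighborhood"]


@dataclass
class ProjectedNeighborhood:
    """2-D PCA coordinates of a center term and its neighbors.

    ``points`` rows: (term, x, y, original_rank, relation_labels) where
    rank 0 is the center term itself and ranks 1..k follow the original
    cosine ordering; ``relation_labels`` lists the relations (if any) that
    link the point to the center term in the knowledge base.
    """

    center_term: str
    points: list[tuple[str, float, float, int, tuple[str, ...]]]
    explained_variance: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"term": t, "x": x, "y": y, "rank": r, "relations": ",".join(labels)}
                for t, x, y, r, labels in self.points
            ]
        )


def _fix_signs(components: np.ndarray) -> np.ndarray:
    fixed = components.copy()
    for i in range(fixed.shape[0]):
        j = int(np.argmax(np.abs(fixed[i])))
        if fixed[i, j] < 0:
            fixed[i] = -fixed[i]
    return fixed


def project_neighborhood(
    E: EmbeddingMatrix,
    term: str,
    k: int,
    kb: RelationKB | None = None,
    scope: str = "local",
) -> ProjectedNeighborhood:
    """PCA-project ``term`` and its top-``k`` cosine neighbors to 2-D.

    ``scope="local"`` (default) fits the PCA on the k+1 selected vectors
    only; ``scope="global"`` fits on the whole vocabulary and then projects
    the selection.  Requires k+1 >= 3, otherwise a 2-component projection
    is underdetermined.
    """
    if term not in E:
        raise KeyError(f"term {term!r} not in vocabulary")
    if k < 1:
        raise ValueError("k must be >= 1")
    if scope not in ("local", "global"):
        raise ValueError("scope must be 'local' or 'global'")
    nbrs = nearest_neighbors_of_term(E, term, k)
    selected = [term] + nbrs.terms
    if len(selected) < 3:
        raise ValueError(f"projection underdetermined: only {len(selected)} points (need >= 3)")
    X_sel = np.vstack([E.vector(t) for t in selected])
    pca = PCA(n_components=2, svd_solver="full")
    if scope == "local":
        pca.fit(X_sel)
    else:
        pca.fit(E.vectors)
    pca.components_ = _fix_signs(pca.components_)
    coords = (X_sel - pca.mean_) @ pca.components_.T
    points = []
    for rank, (t, (x, y)) in enumerate(zip(selected, coords)):
        labels: tuple[str, ...] = ()
        if kb is not None and rank > 0:
            labels = tuple(
                sorted(rel for rel, ts in kb.relations_of(term).items() if t in ts)
            )
        points.append((t, float(x), float(y), rank, labels))
    ev = pca.explained_variance_
    return ProjectedNeighborhood(term, points, (float(ev[0]), float(ev[1])))


def plot_neighborhood(proj: ProjectedNeighborhood, ax=None, max_size: float = 600.0):
    """Scatter the projection; closer original-space ranks get bigger circles.

    Points sharing a relation label share a marker symbol; unlabeled
    neighbors are circles.  Returns the matplotlib Axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    markers = ["o", "s", "^", "D", "v", "P", "X", "*", "<", ">"]
    label_syms: dict[str, str] = {}
    k = max(r for _, _, _, r, _ in proj.points)
    for t, x, y, rank, labels in proj.points:
        if rank == 0:
            ax.scatter([x], [y], s=max_size, marker="*", color="crimson", zorder=3)
        else:
            key = labels[0] if labels else ""
            if key and key not in label_syms:
                label_syms[key] = markers[len(label_syms) % len(markers)]
            size = max_size * (k - rank + 1) / k
            ax.scatter(
                [x], [y], s=size, marker=label_syms.get(key, "o"),
                alpha=0.6, color="steelblue" if not key else None,
                label=key if key and key in label_syms and label_syms[key] else None,
            )
        ax.annotate(t, (x, y), fontsize=8, ha="center", va="bottom")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title(f"Neighborhood of {proj.center_term!r}")
    return ax
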