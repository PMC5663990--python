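"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: nearest-branch labels
are found by a dense brute-force scan over all (voxel, polyline-point)
pairs, and margin shells by explicit pairwise distances to tumor voxels.
"""

import numpy as np
from scipy.spatial.distance import cdist

from sirtdose.graph import densify_polyline


def brute_force_labels(liver_mask, graph, spacing, branch_to_territory,
                       densify_mm=1.0):
    """Nearest-branch territory labels by exhaustive pairwise distances.

    Iterates branches in ascending id with a strict '<' update, so exact
    distance ties keep the lowest branch id — the same documented rule the
    production labeling uses.
    """
    spacing = np.asarray(spacing, float)
    vox = np.argwhere(np.asarray(liver_mask, bool))
    pts = vox * spacing
    best_d = np.full(len(pts), np.inf)
    best_t = np.zeros(len(pts), dtype=np.int32)
    for bid in sorted(b for b in graph.branches if b in branch_to_territory):
        poly = densify_polyline(graph.branches[bid].points, densify_mm)
        d = cdist(pts, poly).min(axis=1)
        upd = d < best_d
        best_d[upd] = d[upd]
        best_t[upd] = branch_to_territory[bid]
    labels = np.zeros(np.asarray(liver_mask).shape, dtype=np.int32)
    labels[tuple(vox.T)] = best_t
    return labels


def brute_force_margin(tumor_mask, liver_mask, margin_mm, spacing):
    """Margin shell by explicit distances to every tumor voxel center."""
    spacing = np.asarray(spacing, float)
    tumor = np.asarray(tumor_mask, bool)
    liver = np.asarray(liver_mask, bool)
    tpts = np.argwhere(tumor) * spacing
    out = np.zeros(tumor.shape, bool)
    if len(tpts) == 0 or margin_mm <= 0:
        return out
    cand = np.argwhere(liver & ~tumor)
    d = cdist(cand * spacing, tpts).min(axis=1)
    sel = cand[d <= margin_mm]
    out[tuple(sel.T)] = True
    return out
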