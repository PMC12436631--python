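"""The 42-column triplet feature encoding.

Per triplet: 11 node-level features for each of the three roles (common, V1,
V2) — hyperbolic coordinates r and theta, the four centralities DC/CC/BC/EC,
an intrinsic-disorder flag, and four subcellular-localization indicators —
plus 3 edge-level features (hyperbolic distance hd, radial difference rd,
angular difference thetad) for each of the three pairs common–V1, common–V2
and V1–V2.  The V1–V2 pair gets edge features even though no edge exists
there: its angular difference is the classifier's dominant signal.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .embedding import EmbeddedNetwork
from .geometry import angular_separation, hyperbolic_distance_arrays
from .triplets import Triplet

__all__ = [
    "LOCALIZATIONS",
    "NODE_FEATURES",
    "EDGE_FEATURES",
    "FEATURE_COLUMNS",
    "KEY_COLUMNS",
    "make_annotation_table",
    "edge_features",
    "build_feature_matrix",
    "attach_labels",
    "randomize_partner_order",
]

LOCALIZATIONS = ("nucleus", "cytoplasm", "endomembrane", "multi_localized")
ROLES = ("common", "v1", "v2")
PAIRS = ("cv1", "cv2", "v1v2")
NODE_FEATURES = ("r", "theta", "DC", "CC", "BC", "EC", "idr") + tuple(
    f"loc_{loc}" for loc in ("nucleus", "cytoplasm", "endomembrane", "multi")
)
EDGE_FEATURES = ("hd", "rd", "thetad")

FEATURE_COLUMNS: list[str] = [f"{role}_{f}" for role in ROLES for f in NODE_FEATURES] + [
    f"{pair}_{f}" for pair in PAIRS for f in EDGE_FEATURES
]
assert len(FEATURE_COLUMNS) == 42 == 3 * 11 + 3 * 3

KEY_COLUMNS = ["common", "v1", "v2"]


def make_annotation_table(
    proteins: Iterable[str],
    idr_flags: dict[str, int] | None = None,
    localization: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-protein annotation table used by the featurizer.

    Proteins absent from the disorder input get ``idr = 0``; proteins absent
    from the localization input are ``unannotated`` (all four indicator
    columns zero downstream).
    """
    idr_flags = idr_flags or {}
    localization = localization or {}
    rows = []
    valid = set(LOCALIZATIONS) | {"unannotated"}
    for p in sorted(set(proteins)):
        loc = localization.get(p, "unannotated")
        if loc not in valid:
            raise ValueError(f"unknown localization {loc!r} for {p}")
        rows.append((p, int(bool(idr_flags.get(p, 0))), loc))
    return pd.DataFrame(rows, columns=["protein", "idr", "localization"]).set_index("protein")


def edge_features(r_a: float, theta_a: float, r_b: float, theta_b: float) -> tuple[float, float, float]:
    """(hd, rd, thetad) for one protein pair."""
    hd = hyperbolic_distance_arrays(r_a, theta_a, r_b, theta_b)
    rd = abs(r_a - r_b)
    thetad = angular_separation(theta_a, theta_b)
    return float(hd), float(rd), float(thetad)


def _node_block(protein: str, coords: pd.DataFrame, cents: pd.DataFrame, ann: pd.DataFrame) -> list[float]:
    if protein not in coords.index:
        raise KeyError(f"protein {protein!r} has no hyperbolic coordinates")
    if protein not in cents.index:
        raise KeyError(f"protein {protein!r} has no centrality row")
    r, theta = float(coords.at[protein, "r"]), float(coords.at[protein, "theta"])
    cent = [float(cents.at[protein, c]) for c in ("DC", "CC", "BC", "EC")]
    if protein in ann.index:
        idr = float(ann.at[protein, "idr"])
        loc = ann.at[protein, "localization"]
    else:
        idr, loc = 0.0, "unannotated"
    loc_flags = [1.0 if loc == name else 0.0 for name in LOCALIZATIONS]
    return [r, theta, *cent, idr, *loc_flags]


def build_feature_matrix(
    triplets: Sequence[Triplet],
    emb: EmbeddedNetwork,
    cents: pd.DataFrame,
    ann: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Featurize triplets into the fixed 42-column schema.

    Returns a DataFrame with the three key columns (common, v1, v2) followed
    by ``FEATURE_COLUMNS`` in order.  Raises ``KeyError`` naming the protein
    if coordinates or centralities are missing.
    """
    if ann is None:
        ann = make_annotation_table([])
    coords = emb.coords
    rows = []
    for t in triplets:
        blocks = [_node_block(p, coords, cents, ann) for p in (t.common, t.v1, t.v2)]
        pair_vals = []
        for a, b in ((t.common, t.v1), (t.common, t.v2), (t.v1, t.v2)):
            pair_vals.extend(
                edge_features(
                    float(coords.at[a, "r"]), float(coords.at[a, "theta"]),
                    float(coords.at[b, "r"]), float(coords.at[b, "theta"]),
                )
            )
        rows.append([t.common, t.v1, t.v2, *blocks[0], *blocks[1], *blocks[2], *pair_vals])
    df = pd.DataFrame(rows, columns=KEY_COLUMNS + FEATURE_COLUMNS)
    assert df.shape[1] == 3 + 42
    return df


def attach_labels(features: pd.DataFrame, labels: dict[Triplet, str]) -> pd.DataFrame:
    """Add a ``label`` column (cooperative / competitive) keyed on the triplet."""
    out = features.copy()
    out["label"] = [
        labels[Triplet(c, v1, v2)] for c, v1, v2 in zip(out["common"], out["v1"], out["v2"])
    ]
    return out


def randomize_partner_order(rows: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Swap V1 and V2 (identities and feature blocks) in half the rows.

    Exactly ``floor(n/2)`` rows, chosen by the seeded generator, have their
    v1/v2 keys, v1/v2 node blocks and common–V1/common–V2 pair blocks
    exchanged; the common block, the symmetric V1–V2 pair block and any label
    column are untouched.  Removes positional bias from the canonical
    ``v1 < v2`` storage order.  Applying the same seeded swap twice restores
    the input.
    """
    out = rows.copy().reset_index(drop=True)
    n = len(out)
    rng = np.random.default_rng(seed)
    chosen = rng.permutation(n)[: n // 2]
    swap_pairs = [("v1", "v2")]
    swap_pairs += [(f"v1_{f}", f"v2_{f}") for f in NODE_FEATURES]
    swap_pairs += [(f"cv1_{f}", f"cv2_{f}") for f in EDGE_FEATURES]
    for a, b in swap_pairs:
        tmp = out.loc[chosen, a].copy()
        out.loc[chosen, a] = out.loc[chosen, b].values
        out.loc[chosen, b] = tmp.values
    return out
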