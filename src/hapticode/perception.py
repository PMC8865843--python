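"""Analyses of the material rating experiment.

Each participant rates every material on seven haptic descriptors
(roughness, orderliness, hardness, temperature, elasticity, friction,
texture) and on similarity to each of seven material categories. Ratings
are z-transformed per (participant, descriptor) to remove subjective scale
use, averaged across participants, and turned into a category-by-category
perceptual distance matrix via the correlation distance

    delta = 2 * (1 - rho),

where rho is the mean Pearson correlation between the descriptor profiles
of materials from the two categories. (``sqrt_variant=True`` computes the
conventional sqrt(2(1-rho)) instead; both are monotone in rho.)

Category-similarity ratings yield a perceived category per material
(per-participant argmax, then across-participant majority vote) and a
between-participant agreement level (leave-one-participant-out majority
prediction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "DESCRIPTORS",
    "RatingTable",
    "z_transform",
    "ratings_pca",
    "perceptual_distance_matrix",
    "assign_perceptual_labels",
    "agreement_level",
]

DESCRIPTORS = (
    "roughness",
    "orderliness",
    "hardness",
    "temperature",
    "elasticity",
    "friction",
    "texture",
)


@dataclass
class RatingTable:
    """Long-format descriptor and category-similarity ratings.

    ``descriptors``: columns (participant_id, material_id, descriptor, value).
    ``categories``: columns (participant_id, material_id, category_id,
    similarity). ``z_transformed`` flags whether descriptor values have been
    standardized per (participant, descriptor).
    """

    descriptors: pd.DataFrame
    categories: pd.DataFrame
    z_transformed: bool = False

    def __post_init__(self):
        need = {"participant_id", "material_id", "descriptor", "value"}
        if not need.issubset(self.descriptors.columns):
            raise ValueError(f"descriptor table needs columns {sorted(need)}")
        need = {"participant_id", "material_id", "category_id", "similarity"}
        if not need.issubset(self.categories.columns):
            raise ValueError(f"category table needs columns {sorted(need)}")

    @property
    def participants(self) -> np.ndarray:
        return np.sort(self.descriptors["participant_id"].unique())

    @property
    def materials(self) -> np.ndarray:
        return np.sort(self.descriptors["material_id"].unique())

    def material_profiles(self) -> pd.DataFrame:
        """Participant-averaged descriptor values: materials x descriptors."""
        wide = self.descriptors.pivot_table(
            index="material_id", columns="descriptor", values="value", aggfunc="mean"
        )
        return wide.reindex(columns=list(DESCRIPTORS))


def z_transform(raw: RatingTable) -> RatingTable:
    """Standardize descriptor ratings per (participant, descriptor) slice.

    Uses the population standard deviation (ddof=0). A constant slice has no
    scale and raises, naming the offending participant and descriptor.
    """
    df = raw.descriptors.copy()
    grouped = df.groupby(["participant_id", "descriptor"])["value"]
    sd = grouped.transform(lambda v: v.std(ddof=0))
    bad = df.loc[sd == 0, ["participant_id", "descriptor"]].drop_duplicates()
    if len(bad):
        p, d = bad.iloc[0]
        raise ValueError(f"constant rating slice for participant {p}, descriptor {d!r}")
    df["value"] = (df["value"] - grouped.transform("mean")) / sd
    return replace(raw, descriptors=df, z_transformed=True)


def ratings_pca(table: RatingTable):
    """PCA of the participant-averaged z-scored descriptor profiles.

    Returns ``(scores, explained_variance_ratio)`` where ``scores`` is a
    materials x 7 DataFrame of principal-component coordinates and the
    variance ratios cover all seven components (they sum to 1).
    """
    if not table.z_transformed:
        table = z_transform(table)
    profiles = table.material_profiles()
    pca = PCA(n_components=None, svd_solver="full").fit(profiles.values)
    scores = pd.DataFrame(
        pca.transform(profiles.values),
        index=profiles.index,
        columns=[f"pc{i + 1}" for i in range(pca.n_components_)],
    )
    return scores, pca.explained_variance_ratio_


def _material_categories(table: RatingTable) -> pd.Series:
    """Ground-truth category per material when carried in the category table."""
    if "true_category_id" in table.categories.columns:
        return (
            table.categories.drop_duplicates("material_id")
            .set_index("material_id")["true_category_id"]
            .sort_index()
        )
    raise ValueError("rating table carries no ground-truth material categories")


def perceptual_distance_matrix(table: RatingTable, material_categories=None,
                               sqrt_variant: bool = False):
    """Category-level perceptual distance matrix from descriptor ratings.

    Every material is summarized by its participant-averaged z-scored
    7-descriptor profile; profiles are correlated for each pair of
    materials; correlations are averaged per category pair (distinct
    material pairs on the diagonal) and mapped through delta = 2(1-rho)
    (or sqrt of that with ``sqrt_variant``).
    """
    from .latent import DistanceMatrix  # local import to avoid a cycle

    if not table.z_transformed:
        raise ValueError("z-transform the ratings before computing perceptual distances")
    cats = pd.Series(material_categories) if material_categories is not None else _material_categories(table)
    profiles = table.material_profiles()
    cats = cats.reindex(profiles.index)
    if cats.isna().any():
        raise ValueError("missing category for some materials")
    values = profiles.values
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = profiles.index[~keep].tolist()
        logger.warning("excluding materials with constant descriptor profiles: %s", dropped)
        values, cats = values[keep], cats[keep]
    rho_mat = np.corrcoef(values)
    labels = np.sort(cats.unique())
    k = len(labels)
    delta = np.zeros((k, k))
    cat_idx = {c: np.flatnonzero(cats.values == c) for c in labels}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            ia, ib = cat_idx[a], cat_idx[b]
            block = rho_mat[np.ix_(ia, ib)]
            if a == b:
                iu = np.triu_indices(len(ia), k=1)
                if iu[0].size == 0:
                    rho = 1.0
                else:
                    rho = float(block[iu].mean())
            else:
                rho = float(block.mean())
            d = 2.0 * (1.0 - rho)
            delta[i, j] = np.sqrt(max(d, 0.0)) if sqrt_variant else d
    return DistanceMatrix(labels=list(labels), values=delta, flavor="perceptual")


def _participant_labels(table: RatingTable) -> pd.DataFrame:
    """Per-(participant, material) argmax category; ties go to the lowest id."""
    cat = table.categories.sort_values(["participant_id", "material_id", "category_id"])

    def pick(group: pd.DataFrame):
        best = group["similarity"].max()
        tied = group.loc[group["similarity"] == best, "category_id"]
        if len(tied) > 1:
            logger.info(
                "argmax tie for participant %s material %s; choosing category %s",
                group["participant_id"].iloc[0], group["material_id"].iloc[0], tied.min(),
            )
        return tied.min()

    out = (
        cat.groupby(["participant_id", "material_id"])[["participant_id", "material_id", "similarity", "category_id"]]
        .apply(pick)
        .rename("label")
        .reset_index()
    )
    return out


def _majority(labels: pd.Series) -> int:
    counts = labels.value_counts()
    best = counts.max()
    tied = sorted(counts[counts == best].index)
    if len(tied) > 1:
        logger.info("majority-vote tie between %s; choosing %s", tied, tied[0])
    return int(tied[0])


def assign_perceptual_labels(table: RatingTable) -> pd.Series:
    """Perceived category per material: per-participant argmax, majority vote."""
    per_part = _participant_labels(table)
    return per_part.groupby("material_id")["label"].apply(_majority).rename("perceptual_label")


def agreement_level(table: RatingTable) -> float:
    """Between-participant agreement in percent.

    Each participant is held out in turn; the majority label of the others
    predicts the held-out participant's own label for each material.
    """
    per_part = _participant_labels(table)
    wide = per_part.pivot(index="material_id", columns="participant_id", values="label")
    participants = wide.columns
    if len(participants) < 2:
        raise ValueError("agreement needs at least two participants")
    correct = total = 0
    for p in participants:
        others = wide.drop(columns=p)
        pred = others.apply(lambda row: _majority(row.dropna()), axis=1)
        correct += int((pred == wide[p]).sum())
        total += len(wide)
    return 100.0 * correct / total
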