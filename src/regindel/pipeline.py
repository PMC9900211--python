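"""Convenience glue: labeled set -> featurized training matrix."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core_io import GenomeSequence
from .features import (
    FeatureMatrix,
    ProfilePredictor,
    SequenceWindow,
    assemble_features,
    filter_and_impute,
    make_window,
)
from .model_eval import FeaturizedSet
from .variant_sets import LabeledSet

__all__ = ["featurize_labeled_set"]

logger = logging.getLogger(__name__)


def featurize_labeled_set(
    labeled: LabeledSet,
    genome: GenomeSequence,
    annotations: pd.DataFrame,
    predictor: ProfilePredictor | None,
    feature_set: str = "generic+ref+alt",
    L: int = 1000,
    impute: bool = True,
) -> FeaturizedSet:
    """Build windows and features for every variant of a labeled set.

    Variants whose window leaves the contig are skipped with a warning.
    The annotation matrix is filtered/imputed here unless the caller
    already did so.
    """
    if impute:
        annotations = filter_and_impute(annotations)
    windows: list[SequenceWindow] = []
    labels: list[int] = []
    for lab, recs in ((1, labeled.positives), (0, labeled.negatives)):
        for rec in recs:
            try:
                windows.append(make_window(genome, rec.variant, L))
            except (ValueError, KeyError) as exc:
                logger.warning("skipping %s: %s", rec.key, exc)
                continue
            labels.append(lab)
    if not windows:
        raise ValueError("no variant produced a valid window")
    X = assemble_features(annotations, windows, predictor, feature_set)
    return FeaturizedSet(
        tissue=labeled.tissue,
        X=X,
        y=np.asarray(labels, dtype=int),
        keys=[w.key for w in windows],
    )
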