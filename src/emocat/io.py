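"""Loaders for externally supplied datasets.

The movie-clip self-report dataset (mean yes/no ratings of 34 emotion
categories and mean ratings of 14 affect dimensions for 2185 clips) is
public but must be downloaded separately; the brain and autonomic datasets
are available only from their original authors. This module validates and
loads locally provided copies so the real-data analyses can be re-run when
the files are present; all tests and acceptance checks run on synthetic
data and never require them.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

CATEGORY_RATINGS_FILE = "category_means.csv"
AFFECT_RATINGS_FILE = "affect_means.csv"


def load_public_clip_ratings(directory) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load (clips x categories, clips x affect) mean-rating CSVs.

    Expects ``category_means.csv`` (values in [0, 1]) and
    ``affect_means.csv`` (values in [1, 9]) with one row per clip and equal
    row counts. Raises ``FileNotFoundError`` when the files are absent.
    """
    directory = Path(directory)
    cat_path = directory / CATEGORY_RATINGS_FILE
    aff_path = directory / AFFECT_RATINGS_FILE
    for path in (cat_path, aff_path):
        if not path.exists():
            raise FileNotFoundError(
                f"{path} not found: the public clip-rating dataset must be "
                "downloaded separately and exported as CSV"
            )
    categories = pd.read_csv(cat_path)
    affect = pd.read_csv(aff_path)
    if len(categories) != len(affect):
        raise ValueError("category and affect tables must have one row per clip each")
    if ((categories < 0) | (categories > 1)).any().any():
        raise ValueError("category means must lie in [0, 1]")
    if ((affect < 1) | (affect > 9)).any().any():
        raise ValueError("affect means must lie in [1, 9]")
    return categories, affect
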