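"""Blocked 3x2x2 factorial design: cells, canonical order, randomization.

The design crosses three cover-letter manipulations of a mailed survey:

* **content** — what recipients are told the survey asks about
  (``combat``, ``sexual_attention``, or a generic ``lifetime`` framing);
* **source** — where recipients are told their name came from
  (an OEF/OIF/OND service roster, ``oef_list``, or a disability-claims
  list, ``claims_list``);
* **incentive** — the promised post-paid honorarium (``usd20`` or
  ``usd40``).

Randomization blocks on gender and splits each block into twelve
equal-sized cells, one per factor combination, via a seeded uniform
shuffle followed by deterministic chunking in canonical cell order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONTENT_LEVELS = ("combat", "sexual_attention", "lifetime")
SOURCE_LEVELS = ("oef_list", "claims_list")
INCENTIVE_LEVELS = ("usd20", "usd40")
BLOCKS = ("men", "women")

FACTOR_LEVELS = {
    "content": CONTENT_LEVELS,
    "source": SOURCE_LEVELS,
    "incentive": INCENTIVE_LEVELS,
}

#: Treatment-coded dummy columns for the seven non-reference arm levels'
#: complement; reference cell is (combat, oef_list, usd20).
ARM_DUMMY_TERMS = (
    "content_sexual_attention",
    "content_lifetime",
    "source_claims_list",
    "incentive_usd40",
)

_KEY_SEP = ":"


class InvalidDesignError(ValueError):
    """Raised when a frame cannot be partitioned into equal design cells."""


@dataclass(frozen=True, order=True)
class FactorLevels:
    """One cell of the factorial design."""

    content: str
    source: str
    incentive: str

    def __post_init__(self) -> None:
        for name, levels in FACTOR_LEVELS.items():
            value = getattr(self, name)
            if value not in levels:
                raise InvalidDesignError(
                    f"unknown {name} level {value!r}; expected one of {levels}"
                )

    def key(self) -> str:
        """Stable string key, e.g. ``'combat:oef_list:usd20'``."""
        return _KEY_SEP.join((self.content, self.source, self.incentive))

    @classmethod
    def from_key(cls, key: str) -> "FactorLevels":
        parts = key.split(_KEY_SEP)
        if len(parts) != 3:
            raise InvalidDesignError(f"malformed cell key {key!r}")
        return cls(*parts)


def build_design() -> list[FactorLevels]:
    """All 12 cells in canonical row-major order.

    Order is content x source x incentive with the level orders of
    :data:`FACTOR_LEVELS`; this order also fixes how shuffled blocks are
    chunked onto cells in :func:`randomize_blocked`.
    """
    return [
        FactorLevels(c, s, i)
        for c, s, i in product(CONTENT_LEVELS, SOURCE_LEVELS, INCENTIVE_LEVELS)
    ]


def randomize_blocked(
    subjects: pd.DataFrame,
    seed: int,
    design: Sequence[FactorLevels] | None = None,
) -> pd.DataFrame:
    """Equal-cell randomization within each gender block.

    Parameters
    ----------
    subjects
        Sampling frame with at least ``subject_id`` and ``block`` columns.
    seed
        Seed for the uniform within-block shuffle. The same seed on the
        same frame yields a byte-identical plan.
    design
        Cells to assign, defaults to :func:`build_design`.

    Returns
    -------
    DataFrame with columns ``subject_id``, ``block``, ``content``,
    ``source``, ``incentive`` — a partition of the input frame where every
    (block, cell) group has exactly ``block_size / n_cells`` subjects.

    Raises
    ------
    InvalidDesignError
        If any block size is not divisible by the number of cells, or
        subject ids are not unique.
    """
    if design is None:
        design = build_design()
    n_cells = len(design)
    if subjects["subject_id"].duplicated().any():
        raise InvalidDesignError("subject_id values must be unique")

    rng = np.random.default_rng(seed)
    pieces = []
    # Fixed block iteration order (known blocks first, extras sorted) so the
    # seed alone determines the plan.
    blocks_present = list(dict.fromkeys(subjects["block"]))
    ordered = [b for b in BLOCKS if b in blocks_present] + sorted(
        b for b in blocks_present if b not in BLOCKS
    )
    for block in ordered:
        ids = subjects.loc[subjects["block"] == block, "subject_id"].to_numpy()
        if len(ids) % n_cells != 0:
            raise InvalidDesignError(
                f"block {block!r} has {len(ids)} subjects, "
                f"not divisible by {n_cells} cells"
            )
        per_cell = len(ids) // n_cells
        shuffled = rng.permutation(ids)
        for j, cell in enumerate(design):
            chunk = shuffled[j * per_cell : (j + 1) * per_cell]
            pieces.append(
                pd.DataFrame(
                    {
                        "subject_id": chunk,
                        "block": block,
                        "content": cell.content,
                        "source": cell.source,
                        "incentive": cell.incentive,
                    }
                )
            )
    plan = pd.concat(pieces, ignore_index=True)
    return plan.sort_values("subject_id", kind="stable", ignore_index=True)


def arm_dummies(assignment: pd.DataFrame) -> pd.DataFrame:
    """Treatment-coded arm indicators (reference: combat / oef_list / usd20).

    Returns ``subject_id`` plus the columns of :data:`ARM_DUMMY_TERMS` as
    0/1 integers, for use as design-complete covariates in imputation and
    selection models.
    """
    out = pd.DataFrame({"subject_id": assignment["subject_id"]})
    out["content_sexual_attention"] = (
        assignment["content"] == "sexual_attention"
    ).astype(int)
    out["content_lifetime"] = (assignment["content"] == "lifetime").astype(int)
    out["source_claims_list"] = (assignment["source"] == "claims_list").astype(int)
    out["incentive_usd40"] = (assignment["incentive"] == "usd40").astype(int)
    return out


def manipulation_strata(assignment: pd.DataFrame) -> list[tuple[str, str, pd.Series]]:
    """The seven single-factor strata as (factor, level, boolean mask) triples.

    Order: 3 content levels, 2 source levels, 2 incentive levels — the
    column order of the published-style report tables.
    """
    out = []
    for factor, levels in FACTOR_LEVELS.items():
        for level in levels:
            out.append((factor, level, assignment[factor] == level))
    return out
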