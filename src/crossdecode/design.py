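"""Experimental design enumeration and pairwise classification schemes.

The experiments this package models use a fully crossed design with three
factors: object category (4 levels, 3 exemplars each), object location
(the 4 screen quadrants) and background clutter (3 levels), giving
48 category-level conditions and 144 exemplar-level condition combinations.

Cross-decoding schemes are built on top of that design: the classified
factor is enumerated as unordered pairs (e.g. the 6 location pairs), and
the transfer factor as ordered train/test pairs with distinct members
(e.g. the 12 category train->test pairs), so that a classifier trained on
one level of the transfer factor is always tested on a different one.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence, Tuple

__all__ = [
    "DesignSpec",
    "ConditionLabel",
    "PairScheme",
    "InvalidDesignError",
    "enumerate_conditions",
    "build_pair_scheme",
    "scheme_cell_count",
    "object_eccentricity",
    "classification_cells",
]

#: Quadrant centres in degrees visual angle, (horizontal, vertical), with the
#: object centre 3 deg away from each central midline.
DEFAULT_OFFSETS_DEG: Mapping[str, Tuple[float, float]] = {
    "left-up": (-3.0, 3.0),
    "left-bottom": (-3.0, -3.0),
    "right-up": (3.0, 3.0),
    "right-bottom": (3.0, -3.0),
}


class InvalidDesignError(ValueError):
    """Raised when a design or scheme specification is internally inconsistent."""


def _check_factor(name: str, values: Sequence[str]) -> Tuple[str, ...]:
    values = tuple(values)
    if not values:
        raise InvalidDesignError(f"factor {name!r} must be non-empty")
    if len(set(values)) != len(values):
        raise InvalidDesignError(f"factor {name!r} contains duplicates: {values}")
    return values


@dataclass(frozen=True)
class DesignSpec:
    """The fully crossed category x location x clutter design.

    Factor order in each list is the canonical order used for every
    enumeration in the package (conditions, pair schemes, RDV entries);
    it is never re-sorted alphabetically so that enumerations align
    across modalities.
    """

    categories: Tuple[str, ...] = ("animals", "cars", "faces", "chairs")
    exemplars_per_category: int = 3
    locations: Tuple[str, ...] = (
        "left-up",
        "left-bottom",
        "right-up",
        "right-bottom",
    )
    location_offsets_deg: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OFFSETS_DEG)
    )
    clutter_levels: Tuple[str, ...] = ("no", "low", "high")
    n_runs: int = 20
    trials_per_condition_per_run: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "categories", _check_factor("categories", self.categories)
        )
        object.__setattr__(
            self, "locations", _check_factor("locations", self.locations)
        )
        object.__setattr__(
            self, "clutter_levels", _check_factor("clutter_levels", self.clutter_levels)
        )
        if self.exemplars_per_category < 1:
            raise InvalidDesignError("exemplars_per_category must be >= 1")
        if self.n_runs < 1 or self.trials_per_condition_per_run < 1:
            raise InvalidDesignError("n_runs and trials_per_condition_per_run must be >= 1")
        for loc in self.locations:
            off = self.location_offsets_deg.get(loc)
            if off is None:
                raise InvalidDesignError(f"missing offset for location {loc!r}")
            h, v = off
            if not (abs(h) < float("inf") and abs(v) < float("inf")):
                raise InvalidDesignError(f"non-finite offset for location {loc!r}")

    @property
    def n_conditions(self) -> int:
        """Number of category-level conditions (48 under the defaults)."""
        return len(self.categories) * len(self.locations) * len(self.clutter_levels)

    def trials_per_condition(self) -> int:
        """Raw trials per category-level condition (60 under the defaults)."""
        return (
            self.n_runs
            * self.trials_per_condition_per_run
            * self.exemplars_per_category
        )

    # -- JSON config round trip -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "categories": list(self.categories),
                "exemplars_per_category": self.exemplars_per_category,
                "locations": [
                    {"name": loc, "offset_deg": list(self.location_offsets_deg[loc])}
                    for loc in self.locations
                ],
                "clutter_levels": list(self.clutter_levels),
                "n_runs": self.n_runs,
                "trials_per_condition_per_run": self.trials_per_condition_per_run,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DesignSpec":
        obj = json.loads(text)
        locs = [entry["name"] for entry in obj["locations"]]
        offsets = {
            entry["name"]: tuple(entry["offset_deg"]) for entry in obj["locations"]
        }
        return cls(
            categories=tuple(obj["categories"]),
            exemplars_per_category=int(obj["exemplars_per_category"]),
            locations=tuple(locs),
            location_offsets_deg=offsets,
            clutter_levels=tuple(obj["clutter_levels"]),
            n_runs=int(obj["n_runs"]),
            trials_per_condition_per_run=int(obj["trials_per_condition_per_run"]),
        )


@dataclass(frozen=True)
class ConditionLabel:
    """One cell of the crossed design, optionally at exemplar resolution."""

    category: str
    location: str
    clutter: str
    exemplar: Optional[int] = None

    def validate(self, design: DesignSpec) -> None:
        if self.category not in design.categories:
            raise InvalidDesignError(f"unknown category {self.category!r}")
        if self.location not in design.locations:
            raise InvalidDesignError(f"unknown location {self.location!r}")
        if self.clutter not in design.clutter_levels:
            raise InvalidDesignError(f"unknown clutter level {self.clutter!r}")
        if self.exemplar is not None and not (
            0 <= self.exemplar < design.exemplars_per_category
        ):
            raise InvalidDesignError(f"exemplar index {self.exemplar} out of range")


def enumerate_conditions(
    design: DesignSpec, level: Literal["category", "exemplar"] = "category"
) -> list[ConditionLabel]:
    """Enumerate the Cartesian product of the design factors in canonical order.

    Order is deterministic: clutter varies slowest, then location, then
    category (with exemplar fastest at exemplar level).  Under the default
    design this yields 48 category-level or 144 exemplar-level labels.
    """
    if level not in ("category", "exemplar"):
        raise InvalidDesignError(f"unknown enumeration level {level!r}")
    labels = []
    for clutter in design.clutter_levels:
        for location in design.locations:
            for category in design.categories:
                if level == "category":
                    labels.append(ConditionLabel(category, location, clutter))
                else:
                    for ex in range(design.exemplars_per_category):
                        labels.append(
                            ConditionLabel(category, location, clutter, exemplar=ex)
                        )
    return labels


PairSubset = Literal["all", "cross_hemifield", "within_hemifield"]


@dataclass(frozen=True)
class PairScheme:
    """Pairwise classification scheme: classified location pairs crossed with
    ordered category train/test pairs.

    ``location_pairs`` are unordered (stored in canonical factor order);
    ``category_train_test_pairs`` are all ordered pairs with distinct members,
    so each unordered category pair appears in both transfer directions.
    """

    location_pairs: Tuple[Tuple[str, str], ...]
    category_train_test_pairs: Tuple[Tuple[str, str], ...]
    pair_subset: PairSubset = "all"

    @property
    def n_cells(self) -> int:
        return len(self.location_pairs) * len(self.category_train_test_pairs)


def _hemifield_subset(
    design: DesignSpec, pairs: Sequence[Tuple[str, str]], kind: str
) -> list[Tuple[str, str]]:
    # cross_hemifield: same vertical offset, opposite horizontal sides;
    # within_hemifield: same horizontal side, different vertical offset.
    out = []
    for a, b in pairs:
        ha, va = design.location_offsets_deg[a]
        hb, vb = design.location_offsets_deg[b]
        if kind == "cross_hemifield" and va == vb and (ha > 0) != (hb > 0):
            out.append((a, b))
        elif kind == "within_hemifield" and (ha > 0) == (hb > 0) and va != vb:
            out.append((a, b))
    return out


def build_pair_scheme(design: DesignSpec, subset: PairSubset = "all") -> PairScheme:
    """Build the pairwise location / ordered category scheme for a design.

    With 4 locations and 4 categories this yields the 6 pairwise location
    classifications, each iterated over the 12 ordered category train/test
    pairs.  ``subset`` restricts the location pairs to the named
    cross-hemifield or within-hemifield splits (2 pairs each under the
    default quadrant geometry); the two diagonal pairs belong only to "all".
    """
    if len(design.locations) < 2 or len(design.categories) < 2:
        raise InvalidDesignError(
            "pair scheme requires at least 2 locations and 2 categories"
        )
    loc_pairs = list(itertools.combinations(design.locations, 2))
    if subset == "all":
        pass
    elif subset in ("cross_hemifield", "within_hemifield"):
        loc_pairs = _hemifield_subset(design, loc_pairs, subset)
    else:
        raise InvalidDesignError(f"unknown pair subset {subset!r}")
    cat_pairs = [
        (a, b) for a in design.categories for b in design.categories if a != b
    ]
    return PairScheme(
        location_pairs=tuple(loc_pairs),
        category_train_test_pairs=tuple(cat_pairs),
        pair_subset=subset,
    )


def scheme_cell_count(scheme: PairScheme, n_iterations: int) -> int:
    """Total classification cells averaged into one reported accuracy.

    72 (6 x 12) for the default scheme at one iteration; 7,200 at the
    100 pseudo-trial randomization iterations used for time-resolved runs.
    """
    if n_iterations < 1:
        raise InvalidDesignError("n_iterations must be >= 1")
    return scheme.n_cells * n_iterations


def object_eccentricity(offset_h: float, offset_v: float) -> float:
    """Eccentricity of an object centre from fixation, in degrees visual angle.

    Exact Euclidean norm; display rounding (e.g. 4.2 for a 3/3 offset) is
    left to the caller.
    """
    import math

    if not (abs(offset_h) < float("inf") and abs(offset_v) < float("inf")):
        raise InvalidDesignError("offsets must be finite")
    return math.hypot(offset_h, offset_v)


def classification_cells(
    scheme: PairScheme, target: Literal["location", "category"] = "location"
) -> list[Tuple[Tuple[str, str], Tuple[str, str]]]:
    """List the (classified pair, transfer train->test pair) cells of a scheme.

    For ``target="location"`` these are the scheme's own fields.  For
    ``target="category"`` the factor roles are reversed: category pairs are
    classified (unordered) and location pairs supply the ordered transfer
    directions — the factor-swapped scheme used for category decoding.
    Both orientations have the same cell count (72 under the defaults).
    """
    if target == "location":
        return [
            (lp, cp)
            for lp in scheme.location_pairs
            for cp in scheme.category_train_test_pairs
        ]
    if target == "category":
        cat_unordered = []
        seen = set()
        for a, b in scheme.category_train_test_pairs:
            key = frozenset((a, b))
            if key not in seen:
                seen.add(key)
                cat_unordered.append((a, b))
        loc_ordered = []
        for a, b in scheme.location_pairs:
            loc_ordered.extend([(a, b), (b, a)])
        return [(cp, lp) for cp in cat_unordered for lp in loc_ordered]
    raise InvalidDesignError(f"unknown target {target!r}")
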