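"""Attribute schema for the inhaler choice experiment.

The experiment describes dry-powder inhalers by six device attributes plus a
monthly out-of-pocket cost attribute. Categorical attributes are dummy-coded
against a declared reference level; the cost attribute is continuous (the
increment, in €/month, over the respondent's current expenditure).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import SchemaError

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"


@dataclass(frozen=True)
class AttributeSpec:
    """One attribute of the choice experiment.

    Parameters
    ----------
    name : str
        Attribute label, used as a column name in exported data.
    kind : {"categorical", "continuous"}
        Categorical attributes are dummy-coded; continuous attributes enter
        the utility linearly (here: cost, in €/month).
    levels : tuple
        Ordered level labels (categorical) or the numeric values the design
        may assign (continuous).
    reference_level : str, optional
        Omitted dummy level; required for categorical attributes.
    """

    name: str
    kind: str
    levels: tuple
    reference_level: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(self.levels))
        if self.kind not in (CATEGORICAL, CONTINUOUS):
            raise SchemaError(f"unknown attribute kind {self.kind!r}")
        if len(self.levels) < 2:
            raise SchemaError(f"attribute {self.name!r} needs >=2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"attribute {self.name!r} has duplicate levels")
        if self.kind == CATEGORICAL:
            if self.reference_level is None:
                raise SchemaError(
                    f"categorical attribute {self.name!r} needs a reference level"
                )
            if self.reference_level not in self.levels:
                raise SchemaError(
                    f"reference level {self.reference_level!r} not among levels "
                    f"of {self.name!r}"
                )

    @property
    def coded_levels(self) -> tuple:
        """Non-reference levels, in declared order (one dummy column each)."""
        if self.kind == CONTINUOUS:
            return ()
        return tuple(l for l in self.levels if l != self.reference_level)


@dataclass(frozen=True)
class Profile:
    """A complete attribute-level assignment describing one inhaler."""

    assignment: Mapping[str, object]

    def __post_init__(self):
        object.__setattr__(self, "assignment", dict(self.assignment))

    def __getitem__(self, name):
        return self.assignment[name]

    def key(self) -> tuple:
        return tuple(sorted(self.assignment.items()))

    def __eq__(self, other):
        return isinstance(other, Profile) and self.key() == other.key()

    def __hash__(self):
        return hash(self.key())


def validate_profile(profile: Profile, attrs: Sequence[AttributeSpec]) -> None:
    names = {a.name for a in attrs}
    assigned = set(profile.assignment)
    if assigned != names:
        raise SchemaError(
            f"profile assigns {sorted(assigned)} but schema requires {sorted(names)}"
        )
    for a in attrs:
        if profile[a.name] not in a.levels:
            raise SchemaError(
                f"value {profile[a.name]!r} not a level of attribute {a.name!r}"
            )


def inhaler_schema() -> list[AttributeSpec]:
    """The seven-attribute inhaler schema used throughout the package.

    Six device attributes (2-3 levels each) plus the monthly cost increment
    with levels +€0 / +€3 / +€6 / +€10. Reference levels are chosen so that
    every coded column corresponds to a reported marginal-utility contrast
    (e.g. "1 step" and "2 to 3 steps" against "more than 4 steps").
    """
    return [
        AttributeSpec(
            "ease_of_use",
            CATEGORICAL,
            ("1 step", "2 to 3 steps", "more than 4 steps"),
            reference_level="more than 4 steps",
        ),
        AttributeSpec(
            "dose_counter", CATEGORICAL, ("yes", "no"), reference_level="no"
        ),
        AttributeSpec(
            "dose_confirmation",
            CATEGORICAL,
            ("taste of lactose", "no taste of lactose"),
            reference_level="no taste of lactose",
        ),
        AttributeSpec(
            "hygiene",
            CATEGORICAL,
            ("can be replaced", "can be washed", "cleaned with a dry cloth"),
            reference_level="cleaned with a dry cloth",
        ),
        AttributeSpec(
            "flexibility",
            CATEGORICAL,
            ("any position", "certain position"),
            reference_level="certain position",
        ),
        AttributeSpec(
            "breathless_use", CATEGORICAL, ("yes", "no"), reference_level="no"
        ),
        AttributeSpec("cost", CONTINUOUS, (0.0, 3.0, 6.0, 10.0)),
    ]


def coded_names(attrs: Sequence[AttributeSpec]) -> list[str]:
    """Column names of the dummy/linear coding, in schema order."""
    names = []
    for a in attrs:
        if a.kind == CONTINUOUS:
            names.append(a.name)
        else:
            names.extend(f"{a.name}[{lvl}]" for lvl in a.coded_levels)
    return names


def code_profile(profile: Profile, attrs: Sequence[AttributeSpec]) -> np.ndarray:
    """Code one profile as a row of the design matrix."""
    row = []
    for a in attrs:
        v = profile[a.name]
        if a.kind == CONTINUOUS:
            row.append(float(v))
        else:
            row.extend(1.0 if v == lvl else 0.0 for lvl in a.coded_levels)
    return np.asarray(row)


def enumerate_full_factorial(attrs: Sequence[AttributeSpec]) -> list[Profile]:
    """All distinct profiles of the schema (the candidate set for design search)."""
    attrs = list(attrs)
    if not attrs:
        raise SchemaError("attribute list is empty")
    names = [a.name for a in attrs]
    return [
        Profile(dict(zip(names, combo)))
        for combo in itertools.product(*(a.levels for a in attrs))
    ]


def schema_to_dict(attrs: Iterable[AttributeSpec]) -> list[dict]:
    out = []
    for a in attrs:
        d = {"name": a.name, "kind": a.kind, "levels": list(a.levels)}
        if a.reference_level is not None:
            d["reference_level"] = a.reference_level
        out.append(d)
    return out


def dump_schema(attrs: Iterable[AttributeSpec], path) -> None:
    with open(path, "w") as fh:
        json.dump(schema_to_dict(attrs), fh, indent=2)


def load_schema(path) -> list[AttributeSpec]:
    with open(path) as fh:
        raw = json.load(fh)
    return [
        AttributeSpec(
            d["name"],
            d["kind"],
            tuple(d["levels"]),
            reference_level=d.get("reference_level"),
        )
        for d in raw
    ]
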