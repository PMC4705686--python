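"""Patterns of interest (POI) over gene-set activity space.

A POI is a predicate on samples, expressed in terms of their gene-set
activities; the samples satisfying it are the "selected" set fed to context
enrichment. Four kinds are supported:

* :class:`IntervalPOI` -- per-set open intervals, conjoined across sets.
  Cutoffs may be raw values, SD offsets from the mean activity, empirical
  quantiles, or normal-tail p-values (:class:`CutoffSpec`).
* :class:`UnionIntervalPOI` -- union of several intervals on one set.
* :class:`PolygonPOI` -- one or more simple polygons in the activity plane
  of two sets; a sample is selected if it falls in (or on the boundary of)
  any polygon. This is the batch equivalent of drawing regions on a
  scatter plot.
* :class:`FormulaPOI` -- a boolean expression over set names, e.g.
  ``"(MYC+2)^2 + (MYC_TG-2)^2*10 < 4"`` (an ellipse).

All interval comparisons are strict (open intervals): samples lying exactly
on a cutoff are not selected. Polygon boundaries, by contrast, count as
inside. Any POI serializes to a JSON document and loads back to an
equivalent predicate.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import shapely
from scipy.stats import norm

from ._errors import FormulaError, ValidationError
from .activity import ActivityMatrix

__all__ = [
    "CutoffSpec",
    "IntervalPOI",
    "UnionIntervalPOI",
    "PolygonPOI",
    "FormulaPOI",
    "resolve_cutoff",
    "default_poi",
    "match_samples",
    "save_poi",
    "load_poi",
    "sanitize_set_name",
]

POI_VERSION = 1

_MODES = ("raw", "sd", "quantile", "normal_p")
_SIDES = ("lower", "upper")


@dataclass(frozen=True)
class CutoffSpec:
    """A cutoff on one set's activity, resolvable against an activity matrix.

    mode
        ``raw``: the value itself. ``sd``: mean + value * SD of the set's
        activities. ``quantile``: empirical quantile (linear interpolation),
        value in [0, 1]. ``normal_p``: tail p-value under a normal fitted to
        the activities, value in (0, 1) -- the upper side gives the point
        with upper-tail probability ``value``, the lower side the point with
        lower-tail probability ``value``.
    side
        Which bound of an interval this cutoff is meant for; only
        ``normal_p`` resolution depends on it.
    """

    mode: str
    value: float
    side: str = "lower"

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValidationError(f"unknown cutoff mode {self.mode!r}")
        if self.side not in _SIDES:
            raise ValidationError(f"cutoff side must be lower|upper, got {self.side!r}")
        if not math.isfinite(self.value):
            raise ValidationError("cutoff value must be finite")
        if self.mode == "quantile" and not 0.0 <= self.value <= 1.0:
            raise ValidationError("quantile cutoff value must be in [0, 1]")
        if self.mode == "normal_p" and not 0.0 < self.value < 1.0:
            raise ValidationError("normal_p cutoff value must be in (0, 1)")

    def to_dict(self) -> dict:
        return {"mode": self.mode, "value": self.value, "side": self.side}

    @classmethod
    def from_dict(cls, d: dict) -> "CutoffSpec":
        return cls(mode=d["mode"], value=float(d["value"]), side=d.get("side", "lower"))


Bound = Union[CutoffSpec, float, None]  # None = unbounded on that side


def resolve_cutoff(spec: CutoffSpec, act: ActivityMatrix, set_name: str) -> float:
    """Turn a cutoff spec into a concrete activity value for one set."""
    if spec.mode == "raw":
        return float(spec.value)
    row = act.row(set_name)
    if spec.mode == "sd":
        if row.size < 2:
            raise ValidationError("sd cutoff needs >=2 samples")
        return float(row.mean() + spec.value * row.std(ddof=1))
    if spec.mode == "quantile":
        return float(np.quantile(row, spec.value))
    # normal_p: fit Normal(mean, sd) and take the requested tail point
    if row.size < 2:
        raise ValidationError("normal_p cutoff needs >=2 samples")
    mean, sd = row.mean(), row.std(ddof=1)
    if spec.side == "upper":
        return float(norm.isf(spec.value, loc=mean, scale=sd))
    return float(norm.ppf(spec.value, loc=mean, scale=sd))


def _resolve_bound(bound: Bound, act: ActivityMatrix, set_name: str,
                   default: float) -> float:
    if bound is None:
        return default
    if isinstance(bound, CutoffSpec):
        return resolve_cutoff(bound, act, set_name)
    return float(bound)


def _bound_to_dict(bound: Bound) -> Union[dict, float, None]:
    if isinstance(bound, CutoffSpec):
        return bound.to_dict()
    return bound


def _bound_from_dict(obj) -> Bound:
    if obj is None:
        return None
    if isinstance(obj, dict):
        return CutoffSpec.from_dict(obj)
    return float(obj)


class _POIBase:
    """Common surface: evaluate to a boolean sample mask; JSON round-trip."""

    def mask(self, act: ActivityMatrix) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def to_dict(self) -> dict:  # pragma: no cover
        raise NotImplementedError


@dataclass
class IntervalPOI(_POIBase):
    """Conjunction of per-set open intervals: set_s in (lower_s, upper_s).

    ``constraints`` is a list of ``(set_name, lower, upper)`` with each bound
    a :class:`CutoffSpec`, a raw float, or ``None`` (unbounded). The resolved
    numeric bounds of the most recent evaluation are kept in ``resolved`` and
    serialized alongside the specs.
    """

    constraints: list[tuple[str, Bound, Bound]]
    resolved: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.constraints:
            raise ValidationError("interval POI needs at least one constraint")
        names = [n for n, _, _ in self.constraints]
        if len(set(names)) != len(names):
            raise ValidationError("interval POI repeats a set name")

    def resolve(self, act: ActivityMatrix) -> dict[str, tuple[float, float]]:
        out: dict[str, tuple[float, float]] = {}
        for name, lo, hi in self.constraints:
            lo_v = _resolve_bound(lo, act, name, -math.inf)
            hi_v = _resolve_bound(hi, act, name, math.inf)
            if not lo_v < hi_v:
                raise ValidationError(
                    f"set {name!r}: resolved interval ({lo_v}, {hi_v}) is empty"
                )
            out[name] = (lo_v, hi_v)
        self.resolved = out
        return out

    def mask(self, act: ActivityMatrix) -> np.ndarray:
        bounds = self.resolve(act)
        m = np.ones(act.n_samples, dtype=bool)
        for name, (lo, hi) in bounds.items():
            row = act.row(name)
            m &= (row > lo) & (row < hi)
        return m

    def to_dict(self) -> dict:
        return {
            "type": "interval",
            "poi_version": POI_VERSION,
            "constraints": [
                {"set": n, "lower": _bound_to_dict(lo), "upper": _bound_to_dict(hi)}
                for n, lo, hi in self.constraints
            ],
            "resolved": {k: list(v) for k, v in self.resolved.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IntervalPOI":
        poi = cls(
            constraints=[
                (c["set"], _bound_from_dict(c["lower"]), _bound_from_dict(c["upper"]))
                for c in d["constraints"]
            ]
        )
        poi.resolved = {k: (v[0], v[1]) for k, v in d.get("resolved", {}).items()}
        return poi


@dataclass
class UnionIntervalPOI(_POIBase):
    """Disjunction of open intervals on a single set's activity."""

    set_name: str
    intervals: list[tuple[Bound, Bound]]
    resolved: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValidationError("union-interval POI needs at least one interval")

    def resolve(self, act: ActivityMatrix) -> list[tuple[float, float]]:
        out = []
        for lo, hi in self.intervals:
            lo_v = _resolve_bound(lo, act, self.set_name, -math.inf)
            hi_v = _resolve_bound(hi, act, self.set_name, math.inf)
            if not lo_v < hi_v:
                raise ValidationError(
                    f"set {self.set_name!r}: resolved interval ({lo_v}, {hi_v}) is empty"
                )
            out.append((lo_v, hi_v))
        self.resolved = out
        return out

    def mask(self, act: ActivityMatrix) -> np.ndarray:
        row = act.row(self.set_name)
        m = np.zeros(act.n_samples, dtype=bool)
        for lo, hi in self.resolve(act):
            m |= (row > lo) & (row < hi)
        return m

    def to_dict(self) -> dict:
        return {
            "type": "union_interval",
            "poi_version": POI_VERSION,
            "set": self.set_name,
            "intervals": [
                {"lower": _bound_to_dict(lo), "upper": _bound_to_dict(hi)}
                for lo, hi in self.intervals
            ],
            "resolved": [list(v) for v in self.resolved],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UnionIntervalPOI":
        poi = cls(
            set_name=d["set"],
            intervals=[
                (_bound_from_dict(c["lower"]), _bound_from_dict(c["upper"]))
                for c in d["intervals"]
            ],
        )
        poi.resolved = [(v[0], v[1]) for v in d.get("resolved", [])]
        return poi


@dataclass
class PolygonPOI(_POIBase):
    """Point-in-polygon selection in the plane of two sets' activities.

    ``polygons`` is a list of vertex lists (>=3 vertices each, simple, i.e.
    non-self-intersecting). A sample is selected if its (x_set, y_set)
    activity point lies inside or on the boundary of any polygon.
    """

    x_set: str
    y_set: str
    polygons: list[list[tuple[float, float]]]

    def __post_init__(self) -> None:
        if not self.polygons:
            raise ValidationError("polygon POI needs at least one polygon")
        self._shapes = []
        for verts in self.polygons:
            if len(verts) < 3:
                raise ValidationError("polygon needs at least 3 vertices")
            shape = shapely.Polygon(verts)
            if not shape.is_valid or shape.area == 0:
                raise ValidationError(
                    f"degenerate or self-intersecting polygon: {verts}"
                )
            self._shapes.append(shape)

    def mask(self, act: ActivityMatrix) -> np.ndarray:
        pts = shapely.points(
            np.column_stack([act.row(self.x_set), act.row(self.y_set)])
        )
        m = np.zeros(act.n_samples, dtype=bool)
        for shape in self._shapes:
            m |= shapely.covers(shape, pts)  # covers: boundary counts as inside
        return m

    def to_dict(self) -> dict:
        return {
            "type": "polygon",
            "poi_version": POI_VERSION,
            "x_set": self.x_set,
            "y_set": self.y_set,
            "polygons": [[list(v) for v in poly] for poly in self.polygons],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolygonPOI":
        return cls(
            x_set=d["x_set"],
            y_set=d["y_set"],
            polygons=[[(float(x), float(y)) for x, y in poly] for poly in d["polygons"]],
        )


# --------------------------------------------------------------------------
# Formula POI: tokenizer + recursive-descent parser + vectorized evaluator.
#
# Precedence (loosest to tightest):  |  <  &  <  comparators  <  + -  <  * /
# <  unary -  <  ^ (right-associative).  So "(A-2)^2*10" squares first, then
# scales, and "-A^2" is -(A^2).

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.\d*|\.\d+|\d+)|(?P<ident>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op><=|>=|[-+*/^()<>&|]))"
)


def sanitize_set_name(name: str) -> str:
    """Replace every non-alphanumeric character with '_' (formula identifiers)."""
    return re.sub(r"[^A-Za-z0-9_]", "_", name)


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise FormulaError(f"unexpected character {text[pos]!r} at position {pos}")
        pos = m.end()
        for kind in ("num", "ident", "op"):
            val = m.group(kind)
            if val is not None:
                tokens.append((kind, val))
                break
    tokens.append(("end", ""))
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> tuple[str, str]:
        return self.tokens[self.i]

    def take(self) -> tuple[str, str]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect_op(self, op: str) -> None:
        kind, val = self.take()
        if kind != "op" or val != op:
            raise FormulaError(f"expected {op!r}, found {val!r}")

    def parse(self):
        node = self.parse_or()
        if self.peek()[0] != "end":
            raise FormulaError(f"trailing input at token {self.peek()[1]!r}")
        return node

    def parse_or(self):
        node = self.parse_and()
        while self.peek() == ("op", "|"):
            self.take()
            node = ("or", node, self.parse_and())
        return node

    def parse_and(self):
        node = self.parse_comparison()
        while self.peek() == ("op", "&"):
            self.take()
            node = ("and", node, self.parse_comparison())
        return node

    def parse_comparison(self):
        node = self.parse_additive()
        kind, val = self.peek()
        if kind == "op" and val in ("<", ">", "<=", ">="):
            self.take()
            return ("cmp", val, node, self.parse_additive())
        return node

    def parse_additive(self):
        node = self.parse_term()
        while True:
            kind, val = self.peek()
            if kind == "op" and val in ("+", "-"):
                self.take()
                node = (val, node, self.parse_term())
            else:
                return node

    def parse_term(self):
        node = self.parse_unary()
        while True:
            kind, val = self.peek()
            if kind == "op" and val in ("*", "/"):
                self.take()
                node = (val, node, self.parse_unary())
            else:
                return node

    def parse_unary(self):
        if self.peek() == ("op", "-"):
            self.take()
            return ("neg", self.parse_unary())
        return self.parse_power()

    def parse_power(self):
        base = self.parse_atom()
        if self.peek() == ("op", "^"):
            self.take()
            # right-associative; exponent may carry its own unary minus
            return ("pow", base, self.parse_unary())
        return base

    def parse_atom(self):
        kind, val = self.take()
        if kind == "num":
            return ("num", float(val))
        if kind == "ident":
            return ("var", val)
        if kind == "op" and val == "(":
            node = self.parse_or()
            self.expect_op(")")
            return node
        raise FormulaError(f"unexpected token {val!r}")


def _eval_node(node, env: dict[str, np.ndarray]):
    op = node[0]
    if op == "num":
        return node[1]
    if op == "var":
        try:
            return env[node[1]]
        except KeyError:
            raise FormulaError(f"unknown gene set identifier {node[1]!r}") from None
    if op == "neg":
        return -_eval_node(node[1], env)
    if op in ("+", "-", "*", "/", "pow"):
        a, b = _eval_node(node[1], env), _eval_node(node[2], env)
        if _is_bool(a) or _is_bool(b):
            raise FormulaError(f"arithmetic {op!r} applied to a boolean subexpression")
        if op == "+":
            return a + b
        if op == "-":
            return a - b
        if op == "*":
            return a * b
        if op == "/":
            return a / b
        return a ** b
    if op == "cmp":
        a, b = _eval_node(node[2], env), _eval_node(node[3], env)
        if _is_bool(a) or _is_bool(b):
            raise FormulaError("comparison applied to a boolean subexpression")
        return {"<": np.less, ">": np.greater,
                "<=": np.less_equal, ">=": np.greater_equal}[node[1]](a, b)
    if op in ("and", "or"):
        a, b = _eval_node(node[1], env), _eval_node(node[2], env)
        if not (_is_bool(a) and _is_bool(b)):
            raise FormulaError(f"'{'&' if op == 'and' else '|'}' needs boolean operands")
        return a & b if op == "and" else a | b
    raise FormulaError(f"internal: unknown node {op!r}")  # pragma: no cover


def _is_bool(x) -> bool:
    return isinstance(x, np.ndarray) and x.dtype == bool


@dataclass
class FormulaPOI(_POIBase):
    """POI given as a boolean formula over sanitized gene-set names.

    Supported syntax: identifiers, numeric literals, ``+ - * / ^`` (with
    ``^`` meaning power), parentheses, comparators ``< > <= >=``, and the
    logical connectives ``&`` and ``|``. The expression must evaluate to a
    boolean per sample.
    """

    expression: str

    def __post_init__(self) -> None:
        self._ast = _Parser(_tokenize(self.expression)).parse()

    def _env(self, act: ActivityMatrix) -> dict[str, np.ndarray]:
        env: dict[str, np.ndarray] = {}
        for name in act.set_names:
            key = sanitize_set_name(name)
            if key in env:
                raise FormulaError(
                    f"set names collide after sanitization: {key!r}"
                )
            env[key] = act.row(name)
        return env

    def mask(self, act: ActivityMatrix) -> np.ndarray:
        result = _eval_node(self._ast, self._env(act))
        if not _is_bool(result):
            raise FormulaError(
                "formula must evaluate to a boolean (use a comparator)"
            )
        return result

    def to_dict(self) -> dict:
        return {
            "type": "formula",
            "poi_version": POI_VERSION,
            "expression": self.expression,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FormulaPOI":
        return cls(expression=d["expression"])


POI = Union[IntervalPOI, UnionIntervalPOI, PolygonPOI, FormulaPOI]

_POI_TYPES: dict[str, type] = {
    "interval": IntervalPOI,
    "union_interval": UnionIntervalPOI,
    "polygon": PolygonPOI,
    "formula": FormulaPOI,
}


def default_poi(set_names: list[str]) -> IntervalPOI:
    """The default pattern: every set's activity above mean + 1 SD.

    This selects samples in which all analyzed gene sets are highly active
    (roughly the upper ~16% per set for near-normal activities).
    """
    if not set_names:
        raise ValidationError("default POI needs at least one gene set")
    return IntervalPOI(
        constraints=[(n, CutoffSpec("sd", 1.0, "lower"), None) for n in set_names]
    )


def match_samples(poi: POI, act: ActivityMatrix) -> np.ndarray:
    """Evaluate a POI against an activity matrix; boolean mask over samples."""
    if not isinstance(poi, _POIBase):
        raise ValidationError(f"not a POI object: {type(poi).__name__}")
    return poi.mask(act)


def save_poi(poi: POI, path) -> None:
    """Serialize any POI kind to a small JSON document."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(poi.to_dict(), fh, indent=1)
        fh.write("\n")


def load_poi(path) -> POI:
    """Load a POI saved by :func:`save_poi`; dispatches on the "type" tag."""
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    if not isinstance(d, dict) or "type" not in d:
        raise ValidationError(f"{path}: not a POI document (missing 'type')")
    cls = _POI_TYPES.get(d["type"])
    if cls is None:
        raise ValidationError(f"{path}: unknown POI type {d['type']!r}")
    try:
        return cls.from_dict(d)
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{path}: malformed POI document: {exc}") from exc
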