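"""Synthetic nonstationary EHR visit streams and visit-table I/O.

The prediction task operates on longitudinal physical-examination
records: each row is one visit of one patient, carrying 20 attributes
(17 numeric vitals/exam values and 3 categorical pattern descriptors)
plus a binary hypertension tag.  Real cohorts of this shape are
credential-restricted, so this module ships a seeded simulator that
emulates the summary structure typical of such cohorts:

* class-conditional attribute means that differ between hypertensive
  and non-hypertensive patients by clinically small shifts (a couple of
  mmHg of systolic pressure, a year or two of age, ...);
* a multivisit count distribution in which most patients have 2-3
  visits and long histories are rare;
* a stream of yearly batches of a few hundred patients whose attribute
  means drift irregularly from batch to batch (a seeded Gaussian random
  walk, optionally plus a deterministic trend).

The same module reads and writes the delimited visit-table format
(``patient_id, visit_index, label`` followed by the 20 attribute
columns) and performs patient-level train/test/validation splits.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AttributeSchema",
    "VisitRecord",
    "BatchStream",
    "SimulationConfig",
    "ConfigError",
    "ParseError",
    "default_schema",
    "default_simulation_config",
    "generate_stream",
    "read_visits",
    "write_visits",
    "split_batch",
    "save_stream",
    "load_stream",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class ParseError(ValueError):
    """Invalid visit table; names the offending 1-based data row."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


# --------------------------------------------------------------------------
# Schema
# --------------------------------------------------------------------------

# Per-attribute simulator defaults: baseline mean for the non-hypertensive
# class, additive shift for the hypertensive class, within-class standard
# deviation, and a plausible clamp range.  The means and class shifts are
# the simulator's reference cohort summary (clinically small differences:
# a couple mmHg of pressure, a year or two of age); the standard
# deviations and bounds are standard clinical ranges.
_NUMERIC_DEFAULTS = {
    # name: (mean_class0, class_effect, sd, low, high)
    "age": (67.9, 2.2, 12.0, 18.0, 100.0),
    "heart_rate": (88.9, -4.2, 15.0, 30.0, 200.0),
    "respiratory_rate": (19.0, -0.1, 4.0, 5.0, 60.0),
    "lhr": (54.6, -0.2, 8.0, 20.0, 100.0),
    "hhr": (121.8, -0.4, 15.0, 60.0, 220.0),
    "lbos": (89.7, 0.0, 4.0, 50.0, 100.0),
    "hbos": (99.0, 0.2, 1.0, 80.0, 100.0),
    "lrr": (9.2, 0.1, 2.0, 0.0, 30.0),
    "hrr": (33.4, -0.4, 6.0, 10.0, 80.0),
    "sbp": (118.2, 5.2, 15.0, 60.0, 250.0),
    "dbp": (62.2, 2.4, 10.0, 30.0, 150.0),
    "mbp": (79.1, 3.2, 11.0, 40.0, 180.0),
    "weight": (93.1, 2.4, 20.0, 30.0, 250.0),
    "cvbp": (10.9, 0.1, 4.0, 0.0, 40.0),
    "labp": (83.1, 0.2, 12.0, 40.0, 160.0),
    "habp": (147.5, 2.1, 18.0, 80.0, 260.0),
    "temperature": (37.9, -1.9, 0.7, 34.0, 42.0),
}

# Attribute order of the visit table (categoricals interleaved where the
# cohort summary lists them).
_ATTRIBUTE_ORDER = [
    "age", "heart_rate", "respiratory_rate", "heart_rhythm", "lhr", "hhr",
    "lbos", "hbos", "lrr", "hrr", "sbp", "dbp", "mbp", "life_pattern",
    "weight", "cvbp", "labp", "habp", "breathing_pattern", "temperature",
]

_CATEGORICAL_LEVELS = ["regular", "irregular", "unknown"]

# Level probabilities per class: hypertensive patients skew toward
# "irregular" patterns; the "unknown" mass is class-independent.
_CAT_PROBS = {0: (0.60, 0.25, 0.15), 1: (0.45, 0.40, 0.15)}


@dataclasses.dataclass(frozen=True)
class AttributeSchema:
    """The 20-attribute visit schema.

    ``kinds[i]`` is ``"numeric"`` or ``"categorical"``;
    ``category_levels`` maps each categorical name to its ordered levels;
    ``numeric_bounds`` maps each numeric name to a (low, high) clamp range.
    """

    names: tuple
    kinds: tuple
    category_levels: dict
    numeric_bounds: dict

    def __post_init__(self):
        if len(self.names) != 20:
            raise ValueError("schema must have exactly 20 attributes")
        if len(set(self.names)) != 20:
            raise ValueError("attribute names must be unique")
        n_cat = sum(k == "categorical" for k in self.kinds)
        if n_cat != 3:
            raise ValueError("schema must have exactly 3 categorical attributes")
        for name, (lo, hi) in self.numeric_bounds.items():
            if not lo < hi:
                raise ValueError(f"bound low >= high for {name}")

    @property
    def numeric_names(self):
        return [n for n, k in zip(self.names, self.kinds) if k == "numeric"]

    @property
    def categorical_names(self):
        return [n for n, k in zip(self.names, self.kinds) if k == "categorical"]

    def embedding_dim(self) -> int:
        """Length of the one-hot/z-score visit embedding."""
        return len(self.numeric_names) + sum(
            len(self.category_levels[c]) for c in self.categorical_names)

    def to_dict(self):
        return {
            "names": list(self.names),
            "kinds": list(self.kinds),
            "category_levels": {k: list(v) for k, v in self.category_levels.items()},
            "numeric_bounds": {k: list(v) for k, v in self.numeric_bounds.items()},
        }

    @classmethod
    def from_dict(cls, d) -> "AttributeSchema":
        return cls(
            names=tuple(d["names"]),
            kinds=tuple(d["kinds"]),
            category_levels={k: list(v) for k, v in d["category_levels"].items()},
            numeric_bounds={k: tuple(v) for k, v in d["numeric_bounds"].items()},
        )


def default_schema() -> AttributeSchema:
    """The default 20-attribute schema (17 numeric + 3 three-level categorical)."""
    kinds = tuple(
        "categorical" if n in ("heart_rhythm", "life_pattern", "breathing_pattern")
        else "numeric" for n in _ATTRIBUTE_ORDER)
    return AttributeSchema(
        names=tuple(_ATTRIBUTE_ORDER),
        kinds=kinds,
        category_levels={c: list(_CATEGORICAL_LEVELS)
                         for c in ("heart_rhythm", "life_pattern", "breathing_pattern")},
        numeric_bounds={n: (v[3], v[4]) for n, v in _NUMERIC_DEFAULTS.items()},
    )


@dataclasses.dataclass
class VisitRecord:
    """One patient visit: 20 raw attribute values plus a binary tag."""

    patient_id: str
    visit_index: int
    values: list
    label: int

    def __post_init__(self):
        if self.visit_index < 1:
            raise ValueError("visit_index must be >= 1")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclasses.dataclass
class BatchStream:
    """An ordered stream of yearly record batches plus its provenance."""

    batches: list            # list of list[VisitRecord]
    batch_labels: list       # e.g. simulated years
    drift_spec: list         # per-batch dict of per-attribute mean offsets
    seed: int
    schema: AttributeSchema


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

def _default_visit_count_distribution():
    # Multivisit census: counts 4479/1124/672/137/47/41/15 patients for
    # 2 / 3 / 4-6 / 6-8 / 8-10 / 10-15 / >15 visits; banded counts are
    # assigned to a representative visit count.
    counts = {2: 4479, 3: 1124, 5: 672, 7: 137, 9: 47, 12: 41, 16: 15}
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the synthetic stream generator.

    ``class_effect`` maps numeric attribute name -> additive mean shift of
    the hypertensive class; ``noise_scale`` multiplies every attribute's
    default within-class standard deviation; ``drift_walk_scale`` is the
    per-batch random-walk step on each attribute mean, in units of that
    attribute's standard deviation.  ``label_flip_prob`` optionally flips
    individual visit tags for stress tests (default keeps labels constant
    per patient).
    """

    n_batches: int = 12
    patients_per_batch: int = 550
    visit_count_distribution: dict = dataclasses.field(
        default_factory=_default_visit_count_distribution)
    class_balance: float = 0.5
    class_effect: dict | None = None      # None -> cohort defaults
    drift_walk_scale: float = 0.3
    drift_trend: dict | None = None       # per-attribute per-batch linear term
    noise_scale: float = 1.0
    label_flip_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_batches < 1:
            raise ConfigError("n_batches", "must be >= 1")
        if self.patients_per_batch < 1:
            raise ConfigError("patients_per_batch", "must be >= 1")
        if not 0.0 <= self.class_balance <= 1.0:
            raise ConfigError("class_balance", "must lie in [0, 1]")
        if self.noise_scale <= 0.0:
            raise ConfigError("noise_scale", "must be > 0")
        if self.drift_walk_scale < 0.0:
            raise ConfigError("drift_walk_scale", "must be >= 0")
        if not 0.0 <= self.label_flip_prob <= 1.0:
            raise ConfigError("label_flip_prob", "must lie in [0, 1]")
        dist = self.visit_count_distribution
        if not dist:
            raise ConfigError("visit_count_distribution", "must be non-empty")
        if any(p < 0 for p in dist.values()) or not np.isclose(sum(dist.values()), 1.0):
            raise ConfigError("visit_count_distribution",
                              "probabilities must be >= 0 and sum to 1")
        if any(k < 1 for k in dist):
            raise ConfigError("visit_count_distribution", "visit counts must be >= 1")


def default_simulation_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(seed=seed)


# Patient-level vs visit-level share of the within-class variance: a stable
# patient offset plus visit-to-visit measurement noise (0.6^2 + 0.8^2 = 1).
_PATIENT_SD_FRAC = 0.6
_VISIT_SD_FRAC = 0.8


def generate_stream(config: SimulationConfig,
                    schema: AttributeSchema | None = None) -> BatchStream:
    """Simulate a seeded nonstationary multivisit stream.

    Deterministic for a fixed ``config.seed``.  Numeric attribute means
    follow a per-attribute Gaussian random walk across batches; the two
    label classes differ by ``class_effect``; each patient keeps one label
    across all visits (unless ``label_flip_prob`` > 0).
    """
    config.validate()
    if schema is None:
        schema = default_schema()
    rng = np.random.default_rng(config.seed)

    numeric = schema.numeric_names
    effects = dict(config.class_effect) if config.class_effect is not None else {
        n: _NUMERIC_DEFAULTS[n][1] for n in numeric}
    base_means = {n: _NUMERIC_DEFAULTS[n][0] for n in numeric}
    sds = {n: _NUMERIC_DEFAULTS[n][2] * config.noise_scale for n in numeric}
    trend = config.drift_trend or {}

    visit_counts = sorted(config.visit_count_distribution)
    visit_probs = np.array([config.visit_count_distribution[k] for k in visit_counts])
    visit_probs = visit_probs / visit_probs.sum()

    batches, drift_spec = [], []
    walk = {n: 0.0 for n in numeric}
    for b in range(config.n_batches):
        if b > 0 and config.drift_walk_scale > 0:
            for n in numeric:
                walk[n] += rng.normal(0.0, config.drift_walk_scale * sds[n])
        offsets = {n: walk[n] + b * trend.get(n, 0.0) for n in numeric}
        drift_spec.append(dict(offsets))

        records = []
        for p in range(config.patients_per_batch):
            pid = f"b{b:02d}p{p:04d}"
            label = int(rng.random() < config.class_balance)
            n_visits = int(rng.choice(visit_counts, p=visit_probs))
            latent = {}
            for n in numeric:
                mu = base_means[n] + offsets[n] + label * effects.get(n, 0.0)
                latent[n] = rng.normal(mu, _PATIENT_SD_FRAC * sds[n])
            for v in range(1, n_visits + 1):
                values = []
                for name, kind in zip(schema.names, schema.kinds):
                    if kind == "numeric":
                        lo, hi = schema.numeric_bounds[name]
                        x = rng.normal(latent[name], _VISIT_SD_FRAC * sds[name])
                        values.append(float(np.clip(x, lo, hi)))
                    else:
                        levels = schema.category_levels[name]
                        probs = np.asarray(_CAT_PROBS[label][:len(levels)], dtype=float)
                        probs = probs / probs.sum()
                        values.append(levels[int(rng.choice(len(levels), p=probs))])
                tag = label
                if config.label_flip_prob > 0 and rng.random() < config.label_flip_prob:
                    tag = 1 - tag
                records.append(VisitRecord(pid, v, values, tag))
        batches.append(records)

    return BatchStream(
        batches=batches,
        batch_labels=[2001 + b for b in range(config.n_batches)],
        drift_spec=drift_spec,
        seed=config.seed,
        schema=schema,
    )


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

_META_COLUMNS = ["patient_id", "visit_index", "label"]


def write_visits(records: list, path, schema: AttributeSchema | None = None) -> None:
    """Write visit records as a UTF-8 CSV with a stable column order."""
    if schema is None:
        schema = default_schema()
    rows = [[r.patient_id, r.visit_index, r.label] + list(r.values)
            for r in records]
    df = pd.DataFrame(rows, columns=_META_COLUMNS + list(schema.names))
    df.to_csv(path, index=False)


def read_visits(path, schema: AttributeSchema | None = None) -> list:
    """Read and validate a visit-record CSV.

    Raises :class:`ParseError` naming the first offending 1-based data row
    on non-finite numerics, unknown categorical levels, or labels outside
    {0, 1}.
    """
    if schema is None:
        schema = default_schema()
    df = pd.read_csv(path, dtype={"patient_id": str},
                     float_precision="round_trip")
    expected = _META_COLUMNS + list(schema.names)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ParseError(0, f"missing column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rd = dict(zip(df.columns, row))
        label = rd["label"]
        if label not in (0, 1):
            raise ParseError(i, f"label {label!r} not in {{0, 1}}")
        try:
            visit_index = int(rd["visit_index"])
        except (TypeError, ValueError):
            raise ParseError(i, f"bad visit_index {rd['visit_index']!r}") from None
        values = []
        for name, kind in zip(schema.names, schema.kinds):
            v = rd[name]
            if kind == "numeric":
                v = float(v)
                if not np.isfinite(v):
                    raise ParseError(i, f"non-finite value for {name}")
                values.append(v)
            else:
                v = str(v)
                if v not in schema.category_levels[name]:
                    raise ParseError(i, f"unknown level {v!r} for {name}")
                values.append(v)
        records.append(VisitRecord(str(rd["patient_id"]), visit_index,
                                   values, int(label)))
    return records


def save_stream(stream: BatchStream, directory) -> Path:
    """Write one CSV per batch plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, batch in enumerate(stream.batches):
        fname = f"batch_{i:03d}.csv"
        write_visits(batch, directory / fname, stream.schema)
        files.append(fname)
    manifest = {
        "schema": stream.schema.to_dict(),
        "files": files,
        "batch_labels": list(stream.batch_labels),
        "drift_spec": stream.drift_spec,
        "seed": stream.seed,
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return mpath


def load_stream(directory) -> BatchStream:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    schema = AttributeSchema.from_dict(manifest["schema"])
    batches = [read_visits(directory / f, schema) for f in manifest["files"]]
    return BatchStream(
        batches=batches,
        batch_labels=manifest["batch_labels"],
        drift_spec=manifest["drift_spec"],
        seed=manifest["seed"],
        schema=schema,
    )


# --------------------------------------------------------------------------
# Splitting
# --------------------------------------------------------------------------

def split_batch(records: list, ratios=(3, 1, 1), rng=None):
    """Patient-level split into train/test/validation partitions.

    All visits of a patient land in one partition; counts follow the
    ratios by largest remainder.  Raises ``ValueError`` when there are
    fewer patients than partitions.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("ratios must be positive")
    by_patient = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    pids = sorted(by_patient)
    k = len(ratios)
    if len(pids) < k:
        raise ValueError(
            f"cannot split {len(pids)} patient(s) into {k} parts")
    order = rng.permutation(len(pids))
    pids = [pids[i] for i in order]

    frac = ratios / ratios.sum()
    raw = frac * len(pids)
    counts = np.floor(raw).astype(int)
    # largest remainder, ties broken by partition order; every partition
    # keeps at least one patient
    remainder = raw - counts
    for idx in np.argsort(-remainder, kind="stable"):
        if counts.sum() == len(pids):
            break
        counts[idx] += 1
    while counts.sum() < len(pids):
        counts[int(np.argmax(remainder))] += 1
    for i in range(k):
        if counts[i] == 0:
            donor = int(np.argmax(counts))
            counts[donor] -= 1
            counts[i] += 1

    parts, start = [], 0
    for c in counts:
        chunk_pids = pids[start:start + c]
        start += c
        chunk = []
        for pid in chunk_pids:
            chunk.extend(sorted(by_patient[pid], key=lambda r: r.visit_index))
        parts.append(chunk)
    return tuple(parts)
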