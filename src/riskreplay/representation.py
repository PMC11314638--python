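"""Visit embeddings and agent state vectors.

A visit record becomes a fixed-length real vector by concatenating, in
schema order, the z-scored numeric attributes and one-hot blocks for
the categorical attributes (d = 17 + 3x3 = 26 with the default
schema).  The agent's state at a patient's t-th visit concatenates the
current visit embedding with the arithmetic mean of the embeddings of
visits 1..t-1; the history half is the zero vector at the first visit,
so every state has length exactly 2d.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .ehr_stream import AttributeSchema, VisitRecord

__all__ = [
    "NormalizationStats",
    "fit_normalizer",
    "embed_record",
    "embed_records",
    "build_state",
    "patient_state_sequence",
]

#: Lower bound on a fitted standard deviation, so constant attributes do
#: not produce divisions by zero.
SD_FLOOR = 1e-6


@dataclasses.dataclass(frozen=True)
class NormalizationStats:
    """Per-numeric-attribute mean and (floored) standard deviation."""

    means: dict
    sds: dict

    def __post_init__(self):
        for name, sd in self.sds.items():
            if sd <= 0:
                raise ValueError(f"sd for {name} must be > 0")


def fit_normalizer(records: list, schema: AttributeSchema) -> NormalizationStats:
    """Estimate per-attribute mean/sd on a reference record set.

    Standard deviations use the population formula (ddof=0) and are
    floored at :data:`SD_FLOOR` for constant attributes.
    """
    if not records:
        raise ValueError("cannot fit a normalizer on an empty record set")
    idx = {name: i for i, name in enumerate(schema.names)}
    means, sds = {}, {}
    for name in schema.numeric_names:
        col = np.array([float(r.values[idx[name]]) for r in records])
        means[name] = float(col.mean())
        sds[name] = float(max(col.std(), SD_FLOOR))
    return NormalizationStats(means=means, sds=sds)


def embed_record(record: VisitRecord, stats: NormalizationStats,
                 schema: AttributeSchema) -> np.ndarray:
    """Embed one visit: z-scored numerics and one-hot categoricals, in
    schema order."""
    out = []
    for name, kind, value in zip(schema.names, schema.kinds, record.values):
        if kind == "numeric":
            out.append((float(value) - stats.means[name]) / stats.sds[name])
        else:
            levels = schema.category_levels[name]
            if value not in levels:
                raise ValueError(f"unknown level {value!r} for {name}")
            onehot = [0.0] * len(levels)
            onehot[levels.index(value)] = 1.0
            out.extend(onehot)
    return np.asarray(out, dtype=float)


def embed_records(records: list, stats: NormalizationStats,
                  schema: AttributeSchema) -> np.ndarray:
    """Stack embeddings for a record list into an (n, d) array."""
    return np.stack([embed_record(r, stats, schema) for r in records]) \
        if records else np.zeros((0, schema.embedding_dim()))


def build_state(history: list, current: np.ndarray) -> np.ndarray:
    """State vector: concat(current, mean of prior visit embeddings).

    ``history`` is the ordered list of earlier visit embeddings; an empty
    history contributes a zero vector (the declared initial state).
    """
    current = np.asarray(current, dtype=float)
    d = current.shape[-1]
    if history:
        hist = np.asarray(history, dtype=float)
        if hist.shape[-1] != d:
            raise ValueError("history and current dimensions differ")
        mean = hist.mean(axis=0)
    else:
        mean = np.zeros(d)
    return np.concatenate([current, mean])


def patient_state_sequence(records: list, stats: NormalizationStats,
                           schema: AttributeSchema) -> list:
    """States for one patient's visits in visit order.

    Returns a list of (state, label) pairs, one per visit; the running
    history mean is updated incrementally.
    """
    ordered = sorted(records, key=lambda r: r.visit_index)
    out = []
    running = None
    for t, rec in enumerate(ordered):
        emb = embed_record(rec, stats, schema)
        if t == 0:
            hist_mean = np.zeros_like(emb)
        else:
            hist_mean = running / t
        out.append((np.concatenate([emb, hist_mean]), rec.label))
        running = emb.copy() if running is None else running + emb
    return out
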