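"""Qualitative EEG feature vocabulary and the VE-ICANS scoring table.

The VE-ICANS score summarises a 15-second, maximally-awake EEG segment as a
single integer: each visually assessed feature (background slowing binned in
1 Hz steps, periodic/rhythmic patterns, voltage attenuation, presence of a
posterior dominant rhythm, ...) carries an integer point value, and the score
is the sum over the features present.  Four patterns of severe encephalopathy
(NCSE, extreme low voltage / electrocerebral silence, burst suppression,
unreactive EEG) bypass the sum and force the maximal score.

Slowing is encoded one-hot within each band: a segment reports at most one
dominant delta frequency, one theta frequency and one alpha frequency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

VOCABULARY_VERSION = "table2-1hz-bins-v1"

ABNORMAL = "abnormal"
NORMAL = "normal"

#: Feature id reserved for electrographic seizures.  Seizures are recorded in
#: data files but are excluded from both scoring and model training because
#: they determine the clinical ICANS grade directly (automatic grade >= 3).
SEIZURE_ID = "seizures"


@dataclass(frozen=True)
class Feature:
    """One entry of the EEG feature vocabulary."""

    id: str
    label: str
    band: str                      # delta | theta | alpha | other
    low_hz: float | None = None    # lower bin bound, where applicable
    high_hz: float | None = None
    polarity: str = ABNORMAL       # abnormal | normal
    severe: bool = False
    group: str | None = None       # ordinal group key (slowing bands)
    model_input: bool = True       # False only for the seizure indicator


class FeatureVocabulary:
    """Ordered collection of features with ordinal-group structure.

    Invariants enforced at construction: unique ids; severe features are
    abnormal; within an ordinal group bins are non-overlapping and totally
    ordered by lower bound.
    """

    def __init__(self, features: Iterable[Feature],
                 version: str = VOCABULARY_VERSION):
        self.features: tuple[Feature, ...] = tuple(features)
        self.version = version
        ids = [f.id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids in vocabulary")
        self._by_id = {f.id: f for f in self.features}
        for f in self.features:
            if f.severe and f.polarity != ABNORMAL:
                raise ValueError(f"severe feature {f.id} must be abnormal")
        for gid, members in self.ordinal_groups().items():
            lows = [self._by_id[m].low_hz for m in members]
            highs = [self._by_id[m].high_hz for m in members]
            if any(l is None for l in lows):
                raise ValueError(f"ordinal group {gid} needs bin bounds")
            for (l1, h1), l2 in zip(zip(lows, highs), lows[1:]):
                if h1 is not None and l2 < l1:
                    raise ValueError(f"ordinal group {gid} not ordered")
                if h1 is not None and l2 < h1:
                    raise ValueError(f"ordinal group {gid} bins overlap")

    def __contains__(self, fid: str) -> bool:
        return fid in self._by_id

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, fid: str) -> Feature:
        try:
            return self._by_id[fid]
        except KeyError:
            raise KeyError(f"unknown feature id: {fid!r}") from None

    @property
    def ids(self) -> list[str]:
        return [f.id for f in self.features]

    def model_ids(self) -> list[str]:
        """Feature ids usable as model inputs (everything but seizures)."""
        return [f.id for f in self.features if f.model_input]

    def severe_ids(self) -> list[str]:
        return [f.id for f in self.features if f.severe]

    def ordinal_groups(self) -> dict[str, list[str]]:
        """Group id -> member feature ids sorted by ascending frequency."""
        groups: dict[str, list[str]] = {}
        for f in self.features:
            if f.group is not None:
                groups.setdefault(f.group, []).append(f.id)
        for gid in groups:
            groups[gid].sort(key=lambda m: self._by_id[m].low_hz)
        return groups


def default_vocabulary() -> FeatureVocabulary:
    """The canonical vocabulary: 15 grading-scheme items, with slowing
    subdivided into 1 Hz bins, plus the seizure indicator carried in data
    files but excluded from modelling."""
    F = Feature
    return FeatureVocabulary([
        F("delta_le_1", "Delta frequency 1 Hz or less", "delta", 0.0, 1.0,
          ABNORMAL, group="delta"),
        F("delta_1_2", "Delta frequency 1-2 Hz", "delta", 1.0, 2.0,
          ABNORMAL, group="delta"),
        F("delta_2_3", "Delta frequency 2-3 Hz", "delta", 2.0, 3.0,
          ABNORMAL, group="delta"),
        F("delta_3_4", "Delta frequency 3-4 Hz", "delta", 3.0, 4.0,
          ABNORMAL, group="delta"),
        F("theta_4_5", "Theta frequency 4-5 Hz", "theta", 4.0, 5.0,
          ABNORMAL, group="theta"),
        F("theta_5_6", "Theta frequency 5-6 Hz", "theta", 5.0, 6.0,
          ABNORMAL, group="theta"),
        F("theta_6_8", "Theta frequency 6-8 Hz", "theta", 6.0, 8.0,
          ABNORMAL, group="theta"),
        F("alpha_le_8", "Alpha frequency 8 Hz or less", "alpha", 0.0, 8.0,
          ABNORMAL, group="alpha"),
        F("alpha_8_9", "Alpha frequency 8-9 Hz", "alpha", 8.0, 9.0,
          NORMAL, group="alpha"),
        F("alpha_ge_9", "Alpha frequency 9 Hz or more", "alpha", 9.0, None,
          NORMAL, group="alpha"),
        F("beta", "Beta oscillations present", "other", polarity=NORMAL),
        F("pdr", "Posterior dominant rhythm present", "other",
          polarity=NORMAL),
        F("awake_signs", "Signs of being awake", "other", polarity=NORMAL),
        F("grda", "Generalized rhythmic delta activity", "other"),
        F("gpds", "Generalized periodic discharges", "other"),
        F("lpds", "Lateralized periodic discharges", "other"),
        F("lrda", "Lateralized rhythmic delta activity", "other"),
        F("mod_low_voltage", "Moderately low voltage (< 20 uV)", "other"),
        F("brief_attenuation", "Intermittent brief attenuation", "other"),
        F("ncse", "Nonconvulsive status epilepticus", "other", severe=True),
        F("ecs", "Low voltage: extreme / electrocerebral silence", "other",
          severe=True),
        F("burst_suppression", "Burst suppression", "other", severe=True),
        F("unreactive", "Unreactive EEG", "other", severe=True),
        F(SEIZURE_ID, "Electrographic seizures", "other", model_input=False),
    ])


class VocabularyMismatchError(KeyError):
    """A feature vector or table references an id outside the vocabulary."""


@dataclass(frozen=True)
class FeatureVector:
    """Binary presence indicators for one patient-day EEG segment."""

    present: frozenset[str]

    @classmethod
    def from_mapping(cls, indicators: Mapping[str, int],
                     vocab: FeatureVocabulary | None = None) -> "FeatureVector":
        vocab = vocab or default_vocabulary()
        present = set()
        for fid, v in indicators.items():
            if fid not in vocab:
                raise VocabularyMismatchError(fid)
            if v not in (0, 1, True, False):
                raise ValueError(f"indicator for {fid} must be 0/1, got {v!r}")
            if v:
                present.add(fid)
        fv = cls(frozenset(present))
        fv.validate(vocab)
        return fv

    def validate(self, vocab: FeatureVocabulary) -> None:
        for fid in self.present:
            if fid not in vocab:
                raise VocabularyMismatchError(fid)
        for gid, members in vocab.ordinal_groups().items():
            if len(self.present.intersection(members)) > 1:
                raise ValueError(
                    f"more than one {gid} frequency bin set: a segment "
                    "reports a single dominant frequency per band")

    def __contains__(self, fid: str) -> bool:
        return fid in self.present


@dataclass
class ScoringTable:
    """Feature -> integer point map with a severe-pattern override.

    ``max_score`` may be an explicit integer or ``None`` (auto), in which case
    the override value is the largest score achievable without severe
    patterns, honouring the one-bin-per-band rule.
    """

    coefficients: dict[str, int]
    severe: set[str] = field(default_factory=set)
    max_score: int | None = None
    provenance: str = ""
    vocabulary_version: str = VOCABULARY_VERSION

    def coefficient(self, fid: str) -> int:
        """Point value of a feature; features dropped by regularisation or
        never considered default to 0."""
        return int(self.coefficients.get(fid, 0))

    def resolved_max_score(self, vocab: FeatureVocabulary | None = None) -> int:
        if self.max_score is not None:
            return int(self.max_score)
        vocab = vocab or default_vocabulary()
        total = 0
        grouped: set[str] = set()
        for gid, members in vocab.ordinal_groups().items():
            grouped.update(members)
            total += max(0, max((self.coefficient(m) for m in members),
                                default=0))
        for fid, c in self.coefficients.items():
            if fid not in grouped and fid not in self.severe and c > 0:
                total += c
        return total

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "features": {k: int(v) for k, v in self.coefficients.items()},
            "severe": sorted(self.severe),
            "max_score": "auto" if self.max_score is None else int(self.max_score),
            "vocabulary_version": self.vocabulary_version,
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringTable":
        ms = d.get("max_score", "auto")
        return cls(
            coefficients={k: int(v) for k, v in d["features"].items()},
            severe=set(d.get("severe", [])),
            max_score=None if ms in ("auto", None) else int(ms),
            provenance=d.get("provenance", ""),
            vocabulary_version=d.get("vocabulary_version", VOCABULARY_VERSION),
        )

    @classmethod
    def from_json(cls, path) -> "ScoringTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def default_table() -> ScoringTable:
    """The published VE-ICANS scoring table.

    Loaded from the packaged table file so that the shipped fixture and the
    library default cannot drift apart.
    """
    ref = resources.files("veicans.data").joinpath("default_table.json")
    with ref.open("r", encoding="utf-8") as fh:
        return ScoringTable.from_dict(json.load(fh))


@dataclass(frozen=True)
class VEICANSScore:
    """Result of scoring one feature vector."""

    value: int
    severe_override: bool
    contributions: dict[str, int]   # feature id -> points, only features present


def score(fv: FeatureVector | Mapping[str, int], table: ScoringTable,
          vocab: FeatureVocabulary | None = None) -> VEICANSScore:
    """Score one patient-day: severe override, else sum of present points."""
    vocab = vocab or default_vocabulary()
    if not isinstance(fv, FeatureVector):
        fv = FeatureVector.from_mapping(fv, vocab)
    else:
        fv.validate(vocab)
    severe_present = [f for f in fv.present if f in table.severe]
    if severe_present:
        return VEICANSScore(
            value=table.resolved_max_score(vocab),
            severe_override=True,
            contributions={f: 0 for f in sorted(fv.present)},
        )
    contributions = {f: table.coefficient(f) for f in sorted(fv.present)
                     if f != SEIZURE_ID}
    return VEICANSScore(value=sum(contributions.values()),
                        severe_override=False,
                        contributions=contributions)


# -- patient-day feature tables (delimited text) --------------------------

#: Non-feature columns of the patient-day table format.
ID_COLUMNS = ("subject_id", "day")
GRADE_COLUMN = "icans"


def validate_feature_frame(df, vocab: FeatureVocabulary | None = None,
                           require_grade: bool = False) -> list[str]:
    """Schema check for a patient-day feature table.

    Required: ``subject_id``, ``day`` and one 0/1 column per model feature
    (the seizure indicator and the ``icans`` grade are optional).  Returns a
    list of human-readable problems; empty means valid.
    """
    vocab = vocab or default_vocabulary()
    problems: list[str] = []
    known = set(vocab.ids) | set(ID_COLUMNS) | {GRADE_COLUMN}
    for col in df.columns:
        if col not in known:
            problems.append(f"unknown column {col!r}")
    for col in ID_COLUMNS:
        if col not in df.columns:
            problems.append(f"missing required column {col!r}")
    for fid in vocab.model_ids():
        if fid not in df.columns:
            problems.append(f"missing feature column {fid!r}")
    if require_grade and GRADE_COLUMN not in df.columns:
        problems.append(f"missing required column {GRADE_COLUMN!r}")
    if problems:
        return problems
    feat_cols = [c for c in df.columns if c in vocab]
    for col in feat_cols:
        bad = ~df[col].isin([0, 1])
        if bad.any():
            row = int(df.index[bad][0])
            problems.append(f"column {col!r}: non-binary value at row {row}")
    if GRADE_COLUMN in df.columns:
        vals = df[GRADE_COLUMN].astype(float)
        ok = (vals >= 0) & (vals <= 4) & ((vals * 2) % 1 == 0)
        if not ok.all():
            row = int(df.index[~ok][0])
            problems.append(f"column 'icans': grade outside 0-4 half-steps "
                            f"at row {row}")
    if not problems:
        dup = df.duplicated(subset=list(ID_COLUMNS))
        if dup.any():
            row = int(df.index[dup][0])
            problems.append(f"duplicate subject-day at row {row}")
        for gid, members in vocab.ordinal_groups().items():
            multi = df[members].sum(axis=1) > 1
            if multi.any():
                row = int(df.index[multi][0])
                problems.append(f"row {row}: more than one {gid} bin set")
    return problems


def read_feature_table(path, vocab: FeatureVocabulary | None = None,
                       require_grade: bool = False):
    """Read and validate a comma-delimited patient-day feature table."""
    import pandas as pd

    df = pd.read_csv(path)
    problems = validate_feature_frame(df, vocab, require_grade=require_grade)
    if problems:
        raise ValueError("invalid feature table:\n  " + "\n  ".join(problems))
    return df


def write_feature_table(df, path) -> None:
    df.to_csv(path, index=False)


def validate_table(table: ScoringTable,
                   vocab: FeatureVocabulary | None = None) -> list[str]:
    """Return every admissibility violation of a scoring table.

    Checks: ids known; coefficients integer; abnormal features >= 0 and
    normal features <= 0; within each slowing group coefficients do not
    increase with frequency; severe features carry no point value (they fire
    the maximal-score override instead).
    """
    vocab = vocab or default_vocabulary()
    violations: list[str] = []
    for fid, c in table.coefficients.items():
        if fid not in vocab:
            violations.append(f"unknown feature id {fid!r}")
            continue
        if float(c) != int(c):
            violations.append(f"{fid}: coefficient {c} is not an integer")
        f = vocab[fid]
        if f.polarity == ABNORMAL and c < 0:
            violations.append(
                f"{fid}: abnormal feature must have coefficient >= 0, got {c}")
        if f.polarity == NORMAL and c > 0:
            violations.append(
                f"{fid}: normal feature must have coefficient <= 0, got {c}")
    for fid in table.severe:
        if fid not in vocab:
            violations.append(f"unknown severe feature id {fid!r}")
        elif fid in table.coefficients:
            violations.append(
                f"{fid}: severe feature must not carry a coefficient")
    for gid, members in vocab.ordinal_groups().items():
        coefs = [table.coefficient(m) for m in members]
        for (m1, c1), (m2, c2) in zip(zip(members, coefs),
                                      list(zip(members, coefs))[1:]):
            if c1 < c2:
                violations.append(
                    f"ordinal violation in {gid}: {m1}={c1} < {m2}={c2} "
                    "(lower frequency must score at least as high)")
    return violations
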