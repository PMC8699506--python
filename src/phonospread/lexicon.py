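"""Lexicon, stimulus-set, and run-configuration I/O.

A lexicon is an ordered collection of (label, phonemic transcription)
entries; the entry order in the file fixes the ``word_id`` of each word.
Transcriptions are sequences of phoneme symbols.  Two encodings are
supported: ``single-char`` (one symbol per character, the style of
Klattese-like machine-readable phonemic alphabets) and
``space-separated`` (multi-character symbols split on spaces, e.g. ARPAbet).

Homophones — distinct labels with identical transcriptions — are legal
and kept as distinct words; :func:`validate_lexicon` flags them so the
caller can decide whether they matter for a given analysis.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import ParseError, ResolutionError, ValidationError

__all__ = [
    "LexiconEntry",
    "Lexicon",
    "StimulusSet",
    "ValidationReport",
    "read_lexicon",
    "write_lexicon",
    "read_stimulus_sets",
    "validate_lexicon",
    "tokenize",
    "detokenize",
]

DIALECTS = ("single-char", "space-separated")


@dataclass(frozen=True)
class LexiconEntry:
    """One word: integer id, orthographic label, phoneme-symbol tuple."""

    word_id: int
    label: str
    transcription: tuple[str, ...]


class Lexicon:
    """Ordered, validated collection of :class:`LexiconEntry`.

    Invariants enforced at construction: word_ids are contiguous from 0
    in entry order, labels are unique, and every transcription has at
    least one symbol.  Duplicate transcriptions (homophones) are allowed.
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        self.entries: tuple[LexiconEntry, ...] = tuple(entries)
        seen_labels: set[str] = set()
        for i, entry in enumerate(self.entries):
            if entry.word_id != i:
                raise ValidationError(
                    f"word_id {entry.word_id} at position {i}: ids must be "
                    "contiguous from 0 in entry order"
                )
            if len(entry.transcription) < 1:
                raise ValidationError(
                    f"entry {entry.label!r} (word_id {i}) has an empty transcription"
                )
            if entry.label in seen_labels:
                raise ValidationError(f"duplicate label {entry.label!r}")
            seen_labels.add(entry.label)
        self._by_label = {e.label: e for e in self.entries}

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, Sequence[str]]]) -> "Lexicon":
        """Build a lexicon from (label, transcription) pairs in order."""
        return cls(
            LexiconEntry(i, label, tuple(trans))
            for i, (label, trans) in enumerate(pairs)
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries)

    def __getitem__(self, word_id: int) -> LexiconEntry:
        return self.entries[word_id]

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Lexicon):
            return NotImplemented
        return self.entries == other.entries

    def __repr__(self) -> str:
        return f"Lexicon({len(self.entries)} entries)"

    def by_label(self, label: str) -> LexiconEntry:
        try:
            return self._by_label[label]
        except KeyError:
            raise ResolutionError(f"word {label!r} not in lexicon") from None

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.entries)


@dataclass(frozen=True)
class StimulusSet:
    """A condition-labeled set of stimulus words.

    ``per_condition_decay`` carries an optional decay proportion used by
    designs in which conditions diffuse under different decay (the
    key/foil manipulation); ``None`` means "use the run default".
    """

    condition_label: str
    words: tuple[str, ...]
    per_condition_decay: float | None = None

    def __post_init__(self):
        if self.per_condition_decay is not None and not (
            0.0 <= self.per_condition_decay <= 1.0
        ):
            raise ValidationError(
                f"decay {self.per_condition_decay} for condition "
                f"{self.condition_label!r} outside [0, 1]"
            )

    def __len__(self) -> int:
        return len(self.words)

    def with_decay(self, d: float | None) -> "StimulusSet":
        """Copy of this set with a different per-condition decay."""
        return replace(self, per_condition_decay=d)


@dataclass
class ValidationReport:
    """Report-only result of :func:`validate_lexicon` (never raises)."""

    homophone_groups: list[tuple[str, ...]] = field(default_factory=list)
    duplicate_labels: list[str] = field(default_factory=list)
    unknown_symbols: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def clean(self) -> bool:
        return (
            not self.homophone_groups
            and not self.duplicate_labels
            and not self.unknown_symbols
        )


def tokenize(text: str, dialect: str = "single-char") -> tuple[str, ...]:
    """Split a transcription field into phoneme symbols per dialect."""
    if dialect == "single-char":
        return tuple(text)
    if dialect == "space-separated":
        return tuple(tok for tok in text.split(" ") if tok)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def detokenize(transcription: Sequence[str], dialect: str = "single-char") -> str:
    joiner = "" if dialect == "single-char" else " "
    return joiner.join(transcription)


def read_lexicon(path: str | Path, dialect: str = "single-char") -> Lexicon:
    """Read a lexicon TSV (header ``label\\ttranscription``).

    Entry order in the file determines word_ids.  Raises
    :class:`ParseError` for malformed lines (with the 1-based line
    number) and :class:`ValidationError` for empty transcriptions.
    """
    path = Path(path)
    pairs: list[tuple[str, tuple[str, ...]]] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if lineno == 1:
                if line.split("\t")[:2] != ["label", "transcription"]:
                    raise ParseError(
                        f"{path}:1: expected header 'label\\ttranscription', "
                        f"got {line!r}"
                    )
                continue
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            label, trans_field = fields[0], fields[1]
            transcription = tokenize(trans_field, dialect)
            if not transcription:
                raise ValidationError(
                    f"{path}:{lineno}: empty transcription for {label!r}"
                )
            pairs.append((label, transcription))
    return Lexicon.from_pairs(pairs)


def write_lexicon(
    lexicon: Lexicon, path: str | Path, dialect: str = "single-char"
) -> None:
    """Write a lexicon as UTF-8 TSV with LF line endings.

    Deterministic: entry order is word_id order, so two writes of the
    same lexicon are byte-identical, and ``read_lexicon(write_lexicon(x))``
    round-trips.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write("label\ttranscription\n")
    for entry in lexicon:
        buf.write(f"{entry.label}\t{detokenize(entry.transcription, dialect)}\n")
    path.write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def read_stimulus_sets(
    path: str | Path, lexicon: Lexicon, dialect: str = "single-char"
) -> list[StimulusSet]:
    """Read a stimulus TSV (header ``condition\\tword[\\tdecay]``).

    One :class:`StimulusSet` per distinct condition, in order of first
    appearance.  Every word must resolve to a lexicon entry; missing
    words raise :class:`ResolutionError` listing them all.  A decay
    value, if present, must be constant within a condition and in [0, 1].
    """
    path = Path(path)
    order: list[str] = []
    words: dict[str, list[str]] = {}
    decays: dict[str, float | None] = {}
    with path.open("r", encoding="utf-8", newline="") as fh:
        header = fh.readline().rstrip("\n").rstrip("\r").split("\t")
        if header[:2] != ["condition", "word"]:
            raise ParseError(
                f"{path}:1: expected header 'condition\\tword[\\tdecay]', "
                f"got {header!r}"
            )
        has_decay = len(header) >= 3 and header[2] == "decay"
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 2 tab-separated fields"
                )
            cond, word = fields[0], fields[1]
            d: float | None = None
            if has_decay and len(fields) >= 3 and fields[2] != "":
                try:
                    d = float(fields[2])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: decay {fields[2]!r} is not a number"
                    ) from None
                if not (0.0 <= d <= 1.0):
                    raise ValidationError(
                        f"{path}:{lineno}: decay {d} outside [0, 1]"
                    )
            if cond not in words:
                order.append(cond)
                words[cond] = []
                decays[cond] = d
            elif decays[cond] != d:
                raise ValidationError(
                    f"{path}:{lineno}: decay for condition {cond!r} is not "
                    f"constant ({decays[cond]} vs {d})"
                )
            words[cond].append(word)

    missing = sorted(
        {w for ws in words.values() for w in ws if w not in lexicon}
    )
    if missing:
        raise ResolutionError(
            f"stimulus words not in lexicon: {', '.join(missing)}"
        )
    return [
        StimulusSet(cond, tuple(words[cond]), decays[cond]) for cond in order
    ]


def validate_lexicon(
    lexicon: Lexicon, alphabet: Iterable[str] | None = None
) -> ValidationReport:
    """Report homophones, duplicate labels, and out-of-alphabet symbols.

    Report-only: the lexicon constructor already rejects structural
    violations; this surfaces the soft issues a curator should review.
    ``alphabet``, if given, declares the legal phoneme-symbol inventory.
    """
    report = ValidationReport()
    by_transcription: dict[tuple[str, ...], list[str]] = {}
    for entry in lexicon:
        by_transcription.setdefault(entry.transcription, []).append(entry.label)
    for trans, labels in by_transcription.items():
        if len(labels) > 1:
            report.homophone_groups.append(tuple(labels))
    if alphabet is not None:
        allowed = set(alphabet)
        for entry in lexicon:
            bad = tuple(s for s in entry.transcription if s not in allowed)
            if bad:
                report.unknown_symbols[entry.label] = bad
    return report


def read_config(path: str | Path) -> Mapping[str, object]:
    """Read a run configuration (YAML or JSON) into a plain mapping.

    Recognized keys: activation, retention, decay, suppress, time, seed.
    """
    import yaml

    with Path(path).open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return data
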