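"""Condition codelists.

Codes are opaque strings with no terminology semantics: synthetic data and
codelists simply share a namespace declared in the run configuration.  Two
kinds of lists exist — ``morbidity`` (diagnosis/symptom codes) and
``prescription`` (drug issue codes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)

VALID_KINDS = frozenset({"morbidity", "prescription"})
_COLUMNS = ["list_name", "kind", "code"]


@dataclass(frozen=True)
class Codelist:
    name: str
    kind: str
    codes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValidationError(
                f"codelist {self.name!r}: unknown kind {self.kind!r} "
                f"(expected one of {sorted(VALID_KINDS)})"
            )
        if not self.codes:
            raise ValidationError(f"codelist {self.name!r} is empty")

    def __contains__(self, code: str) -> bool:
        return code in self.codes


def load_codelists(path) -> dict[str, Codelist]:
    """Read a codelist CSV (header ``list_name,kind,code``) into a mapping
    name -> :class:`Codelist`.

    Duplicate (list, code) rows are collapsed with a logged warning; an
    empty file, a missing column or an unknown kind raises
    :class:`ValidationError`.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"codelist file {path}: missing column(s) {missing}")
    if df.empty:
        raise ValidationError(f"codelist file {path}: no rows")
    dup = df.duplicated(subset=_COLUMNS)
    if dup.any():
        log.warning(
            "codelist file %s: %d duplicate code row(s) collapsed", path, int(dup.sum())
        )
        df = df[~dup]
    out: dict[str, Codelist] = {}
    for (name, kind), grp in df.groupby(["list_name", "kind"], sort=False):
        if name in out:
            raise ValidationError(f"codelist {name!r} declared with two kinds")
        out[name] = Codelist(name=name, kind=kind, codes=frozenset(grp["code"]))
    return out


def save_codelists(codelists: dict[str, Codelist], path) -> Path:
    """Write the inverse of :func:`load_codelists`; round-trips at set level."""
    rows = [
        {"list_name": cl.name, "kind": cl.kind, "code": code}
        for cl in codelists.values()
        for code in sorted(cl.codes)
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)
    return path
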