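"""File formats and session persistence.

* Manifest: CSV with columns ``item_id[,path][,anchor_label]``; extra
  columns are preserved but ignored.  Anchor labels are normalized to
  the canonical vocabulary {too_basal, lv, too_apical}.
* Session file: JSON with a schema version, the config, per-item state,
  the event log and the RNG state, so ``load(save(s))`` is bit-identical
  (including future random draws).
* Exports: ranking CSV ``item_id,rank,rating,view_count,volatility`` and
  labels CSV ``item_id,class_label,rank``.

All writes go to a temporary file in the target directory followed by
an atomic rename, so a failed operation never leaves a partial file.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .discretize import ClassAssignment
from .rating import (
    CLASS_LABELS,
    BatchRanking,
    ItemState,
    Session,
    SessionConfig,
    ranked_items,
)

SESSION_SCHEMA_VERSION = 1

#: Normalization table for common spellings of the three class labels.
LABEL_ALIASES = {
    "too_basal": "too_basal", "too basal": "too_basal", "too-basal": "too_basal",
    "basal": "too_basal",
    "lv": "lv", "in the lv": "lv", "in_the_lv": "lv", "in-the-lv": "lv",
    "too_apical": "too_apical", "too apical": "too_apical",
    "too-apical": "too_apical", "apical": "too_apical",
}


def normalize_label(raw: str) -> str:
    """Map a free-text class label to the canonical vocabulary."""
    key = str(raw).strip().lower()
    if key not in LABEL_ALIASES:
        raise ValueError(f"unrecognized class label: {raw!r}")
    return LABEL_ALIASES[key]


@dataclass(frozen=True)
class ManifestRow:
    item_id: str
    path: str | None = None
    anchor_label: str | None = None


@dataclass(frozen=True)
class Manifest:
    rows: tuple[ManifestRow, ...]

    @property
    def item_ids(self) -> list[str]:
        return [r.item_id for r in self.rows]

    @property
    def anchors(self) -> dict[str, str]:
        return {r.item_id: r.anchor_label for r in self.rows if r.anchor_label}


def read_manifest(path: str | Path) -> Manifest:
    """Read and validate an item manifest CSV."""
    df = pd.read_csv(path, dtype=str)
    if "item_id" not in df.columns:
        raise ValueError(f"{path}: missing required header column 'item_id'")
    rows: list[ManifestRow] = []
    seen: dict[str, int] = {}
    for i, rec in enumerate(df.itertuples(index=False), start=2):  # row 1 = header
        item_id = getattr(rec, "item_id")
        if pd.isna(item_id) or not str(item_id).strip():
            raise ValueError(f"{path}: empty item_id on row {i}")
        item_id = str(item_id).strip()
        if item_id in seen:
            raise ValueError(
                f"{path}: duplicate item_id {item_id!r} on row {i} (first seen row {seen[item_id]})")
        seen[item_id] = i
        img_path = getattr(rec, "path", None) if "path" in df.columns else None
        img_path = None if (img_path is None or pd.isna(img_path)) else str(img_path)
        anchor = getattr(rec, "anchor_label", None) if "anchor_label" in df.columns else None
        if anchor is not None and not pd.isna(anchor) and str(anchor).strip():
            try:
                anchor = normalize_label(anchor)
            except ValueError as exc:
                raise ValueError(f"{path}: row {i}: {exc}") from exc
        else:
            anchor = None
        rows.append(ManifestRow(item_id=item_id, path=img_path, anchor_label=anchor))
    if not rows:
        raise ValueError(f"{path}: manifest has no items")
    return Manifest(rows=tuple(rows))


def _atomic_write_text(path: Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def save_session(session: Session, path: str | Path) -> None:
    """Serialize the full session (including RNG state) to JSON."""
    payload = {
        "schema_version": SESSION_SCHEMA_VERSION,
        "config": asdict(session.config),
        "items": [asdict(s) for s in session.items.values()],
        "event_log": [
            {"ordered_items": list(e.ordered_items), "annotator_id": e.annotator_id,
             "timestamp": e.timestamp}
            for e in session.event_log
        ],
        "pair_update_count": session.pair_update_count,
        "rng_state": session.rng.bit_generator.state,
    }
    _atomic_write_text(Path(path), json.dumps(payload, indent=1))


def load_session(path: str | Path) -> Session:
    """Reconstruct a session saved by :func:`save_session`."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not a valid session file ({exc})") from exc
    version = payload.get("schema_version")
    if version != SESSION_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: unsupported session schema version {version!r} "
            f"(this reader supports {SESSION_SCHEMA_VERSION})")
    config = SessionConfig(**payload["config"])
    items = {
        rec["item_id"]: ItemState(
            item_id=rec["item_id"], rating=rec["rating"], rank=rec["rank"],
            view_count=rec["view_count"], volatility=rec["volatility"],
            surprise_history=list(rec["surprise_history"]))
        for rec in payload["items"]
    }
    rng = np.random.default_rng(0)
    rng.bit_generator.state = payload["rng_state"]
    session = Session(items=items, config=config, rng=rng)
    session.event_log = [
        BatchRanking(ordered_items=tuple(e["ordered_items"]),
                     annotator_id=e["annotator_id"], timestamp=e["timestamp"])
        for e in payload["event_log"]
    ]
    session.pair_update_count = payload["pair_update_count"]
    return session


def export_ranking(session: Session, path: str | Path) -> None:
    """Write the current ranking as CSV, rank 1 (most basal) first."""
    df = pd.DataFrame(
        [{"item_id": s.item_id, "rank": s.rank, "rating": s.rating,
          "view_count": s.view_count, "volatility": s.volatility}
         for s in ranked_items(session)])
    _atomic_write_text(Path(path), df.to_csv(index=False))


def export_labels(assignments: Iterable[ClassAssignment], path: str | Path) -> None:
    """Write discrete class labels as CSV ``item_id,class_label,rank``."""
    df = pd.DataFrame(
        [{"item_id": a.item_id, "class_label": a.class_label, "rank": a.rank}
         for a in assignments])
    _atomic_write_text(Path(path), df.to_csv(index=False))


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a labels CSV (``item_id,class_label``) into a dict."""
    df = pd.read_csv(path, dtype=str)
    for col in ("item_id", "class_label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    labels: dict[str, str] = {}
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        item_id = str(rec.item_id).strip()
        if item_id in labels:
            raise ValueError(f"{path}: duplicate item_id {item_id!r} on row {i}")
        labels[item_id] = normalize_label(rec.class_label)
    if not labels:
        raise ValueError(f"{path}: no labels")
    return labels
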