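"""Record cache: session-scoped identity keys, timestamped envelopes, disk
persistence, time-based expiration and atomic refresh.

Keys are computed from ``(record_type, record_id)`` with a per-session salt,
so they are deterministic within one process but deliberately unstable
across sessions; the on-disk format is keyed by ``(type, id)`` only and keys
are recomputed on load.  The disk format is the snapshot JSON dialect plus a
small metadata header, so caches stay human-inspectable.
"""

from __future__ import annotations

import json
import os
import random
import tempfile
import urllib.request
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Union

from . import records as _records
from .records import (
    KbRecord,
    RecordCollection,
    RecordIdentifier,
    resolve_links,
    snapshot_from_dict,
    snapshot_to_dict,
)

CACHE_FORMAT = "kb-cache"
CACHE_VERSION = 1
DEFAULT_EXPIRY_DAYS = 7.0

# per-session salt: equal (type, id) pairs hash equal within one process only
_SESSION_SALT = random.SystemRandom().getrandbits(64)


class CacheError(Exception):
    """Base class for cache failures."""


class CacheCorruptError(CacheError):
    """The cache file exists but cannot be read back."""


class CacheVersionError(CacheError):
    """The cache file was written by an incompatible format version."""


class ClockSkewError(CacheError):
    """`now` precedes the cache build time."""


class RetrievalError(CacheError):
    """The snapshot source could not be read; any existing cache is untouched."""


def record_key(record_type: str, record_id: int) -> int:
    """Session-scoped opaque key for a record identity.

    Partial and full records with equal ``(type, id)`` yield the same key.
    Keys are NOT stable across processes and must never be persisted.
    """
    RecordIdentifier(record_type, record_id)  # validates
    return hash((_SESSION_SALT, record_type, record_id))


def _utcnow() -> datetime:
    return datetime.now(timezone.utc)


@dataclass
class CacheEnvelope:
    """A record collection plus its build timestamp and expiry policy."""

    built_at: datetime
    records: RecordCollection
    expiry_days: float = DEFAULT_EXPIRY_DAYS
    _by_key: dict[int, KbRecord] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.expiry_days <= 0:
            raise ValueError(f"expiry_days must be positive, got {self.expiry_days}")
        if self.built_at.tzinfo is None:
            self.built_at = self.built_at.replace(tzinfo=timezone.utc)

    def get_by_key(self, key: int) -> KbRecord | None:
        if not self._by_key:
            self._by_key = {
                record_key(r.type, r.id): r for r in self.records
            }
        return self._by_key.get(key)


def build_envelope(
    collection: RecordCollection,
    built_at: datetime | None = None,
    expiry_days: float = DEFAULT_EXPIRY_DAYS,
) -> CacheEnvelope:
    return CacheEnvelope(
        built_at=built_at or _utcnow(), records=collection, expiry_days=expiry_days
    )


def is_stale(
    envelope: CacheEnvelope,
    now: datetime | None = None,
    expiry_days: float | None = None,
) -> bool:
    """True iff ``now - built_at`` strictly exceeds the expiry window.

    The boundary is inclusive of validity: a cache exactly ``expiry_days``
    old is still fresh.
    """
    now = now or _utcnow()
    if now.tzinfo is None:
        now = now.replace(tzinfo=timezone.utc)
    if now < envelope.built_at:
        raise ClockSkewError(
            f"now ({now.isoformat()}) precedes cache build time "
            f"({envelope.built_at.isoformat()})"
        )
    days = envelope.expiry_days if expiry_days is None else expiry_days
    if days <= 0:
        raise ValueError(f"expiry_days must be positive, got {days}")
    return (now - envelope.built_at) > timedelta(days=days)


# ---------------------------------------------------------------------------
# Persistence


def save_cache(envelope: CacheEnvelope, path: Union[str, os.PathLike]) -> None:
    """Atomically write an envelope to ``path`` (snapshot JSON + metadata)."""
    doc = {
        "format": CACHE_FORMAT,
        "version": CACHE_VERSION,
        "built_at": envelope.built_at.isoformat(),
        "expiry_days": envelope.expiry_days,
        "snapshot": snapshot_to_dict(envelope.records),
    }
    _atomic_write(Path(path), json.dumps(doc, sort_keys=True).encode("utf-8"))


def load_cache(path: Union[str, os.PathLike]) -> CacheEnvelope:
    """Load an envelope; session keys are recomputed, never read from disk."""
    path = Path(path)
    try:
        raw = path.read_bytes()
        doc = json.loads(raw)
    except (OSError, json.JSONDecodeError) as exc:
        raise CacheCorruptError(f"cannot read cache file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != CACHE_FORMAT:
        raise CacheCorruptError(f"{path} is not a {CACHE_FORMAT} file")
    if doc.get("version") != CACHE_VERSION:
        raise CacheVersionError(
            f"cache file {path} has format version {doc.get('version')!r}, "
            f"expected {CACHE_VERSION}"
        )
    try:
        built_at = datetime.fromisoformat(doc["built_at"])
        expiry_days = float(doc.get("expiry_days", DEFAULT_EXPIRY_DAYS))
        collection = resolve_links(snapshot_from_dict(doc["snapshot"]))
    except (KeyError, ValueError, _records.SnapshotSchemaError) as exc:
        raise CacheCorruptError(f"cache file {path} is corrupt: {exc}") from exc
    return CacheEnvelope(built_at=built_at, records=collection, expiry_days=expiry_days)


def _atomic_write(path: Path, data: bytes) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def default_cache_path() -> Path:
    """Platform-appropriate cache file location, overridable via the
    ``KBMATCH_CACHE`` environment variable."""
    override = os.environ.get("KBMATCH_CACHE")
    if override:
        return Path(override)
    base = os.environ.get("XDG_CACHE_HOME")
    root = Path(base) if base else Path.home() / ".cache"
    return root / "kbmatch" / "cache.json"


# ---------------------------------------------------------------------------
# Refresh from a snapshot source


@dataclass(frozen=True)
class SnapshotSource:
    """A place to fetch snapshots from: a local path or an http(s)/file URL."""

    location: str

    def fetch(self) -> bytes:
        loc = self.location
        try:
            if loc.startswith(("http://", "https://", "file://")):
                with urllib.request.urlopen(loc) as resp:  # noqa: S310
                    return resp.read()
            with open(loc, "rb") as fh:
                return fh.read()
        except Exception as exc:
            raise RetrievalError(f"cannot retrieve snapshot from {loc}: {exc}") from exc


def refresh(
    source: Union[SnapshotSource, str, os.PathLike],
    cache_path: Union[str, os.PathLike, None] = None,
    expiry_days: float = DEFAULT_EXPIRY_DAYS,
) -> CacheEnvelope:
    """Fetch a fresh snapshot, build an envelope, and atomically replace the
    on-disk cache.  On any failure the previous cache file is left intact.
    """
    if not isinstance(source, SnapshotSource):
        source = SnapshotSource(str(source))
    data = source.fetch()
    try:
        collection = resolve_links(_records.parse_snapshot(data))
    except (_records.SnapshotParseError, _records.SnapshotSchemaError) as exc:
        raise RetrievalError(f"snapshot from {source.location} is unusable: {exc}") from exc
    envelope = CacheEnvelope(
        built_at=_utcnow(), records=collection, expiry_days=expiry_days
    )
    if cache_path is not None:
        save_cache(envelope, cache_path)
    return envelope
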