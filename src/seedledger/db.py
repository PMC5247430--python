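"""The embedded database container.

One laboratory = one single-file SQLite database.  :class:`SeedDatabase`
wraps the connection together with the logged-in account; every operation
function in the sibling modules takes it as first argument, scanpy-style.

Opening a path that does not exist (or ``":memory:"``) bootstraps the schema,
seeds the default vocabularies and creates the given login as the first
ADMINISTRATOR account.  Seed-batch identifiers use SQLite's AUTOINCREMENT
rowid, which the engine guarantees to be strictly increasing and never
reused, even after deletions.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import os
import secrets
import sqlite3
from typing import Any, Iterable

from .errors import AuthorizationError, ConflictError, NotFoundError
from .models import FeatureCategory, Role, VocabCategory

_SCHEMA = """
PRAGMA foreign_keys = ON;

CREATE TABLE users (
  id            INTEGER PRIMARY KEY,
  login         TEXT COLLATE NOCASE NOT NULL UNIQUE,
  role          TEXT NOT NULL CHECK (role IN ('READER','WRITER','ADMINISTRATOR')),
  password_hash TEXT NOT NULL DEFAULT '',
  salt          TEXT NOT NULL DEFAULT ''
);

CREATE TABLE vocab (
  id               INTEGER PRIMARY KEY,
  category         TEXT NOT NULL,
  value            TEXT COLLATE NOCASE NOT NULL,
  active           INTEGER NOT NULL DEFAULT 1,
  linked_species   INTEGER REFERENCES vocab(id),
  feature_category TEXT,
  reserved         INTEGER NOT NULL DEFAULT 0,
  UNIQUE (category, value)
);

CREATE TABLE lines (
  id            INTEGER PRIMARY KEY,
  name          TEXT NOT NULL,
  person_id     INTEGER NOT NULL REFERENCES vocab(id),
  species_id    INTEGER NOT NULL REFERENCES vocab(id),
  ecotype_id    INTEGER REFERENCES vocab(id),
  ecotype_label TEXT NOT NULL DEFAULT '',
  origin        TEXT NOT NULL DEFAULT '',
  creation_mode TEXT NOT NULL,
  mta_protected INTEGER NOT NULL DEFAULT 0,
  mta_details   TEXT NOT NULL DEFAULT '',
  locked        INTEGER NOT NULL DEFAULT 0
);

CREATE TABLE line_parents (
  child_id  INTEGER NOT NULL REFERENCES lines(id),
  parent_id INTEGER NOT NULL REFERENCES lines(id),
  role      TEXT NOT NULL,
  batch_id  INTEGER REFERENCES seed_batches(system_id) ON DELETE SET NULL,
  PRIMARY KEY (child_id, role)
);

CREATE TABLE features (
  id                  INTEGER PRIMARY KEY,
  origin_line         INTEGER NOT NULL REFERENCES lines(id),
  designation         TEXT NOT NULL,
  category            TEXT NOT NULL,
  gene                TEXT NOT NULL DEFAULT '',
  mutation_method     INTEGER REFERENCES vocab(id),
  method_reference    INTEGER REFERENCES vocab(id),
  sequence            TEXT NOT NULL DEFAULT '',
  resistance          INTEGER REFERENCES vocab(id),
  agro_strain         INTEGER REFERENCES vocab(id),
  genotyping_protocol TEXT NOT NULL DEFAULT '',
  provenance          TEXT NOT NULL DEFAULT ''
);

CREATE TABLE plants (
  id                  INTEGER PRIMARY KEY,
  line_id             INTEGER NOT NULL REFERENCES lines(id),
  personal_identifier TEXT NOT NULL,
  generation_label    TEXT NOT NULL DEFAULT '',
  phenotype_note      TEXT NOT NULL DEFAULT '',
  notebook_ref        TEXT NOT NULL DEFAULT '',
  person_id           INTEGER REFERENCES vocab(id),
  locked              INTEGER NOT NULL DEFAULT 0
);

CREATE TABLE plant_genotypes (
  plant_id   INTEGER NOT NULL REFERENCES plants(id) ON DELETE CASCADE,
  feature_id INTEGER NOT NULL REFERENCES features(id),
  state      TEXT NOT NULL,
  PRIMARY KEY (plant_id, feature_id)
);

CREATE TABLE insertion_sites (
  plant_id          INTEGER NOT NULL REFERENCES plants(id) ON DELETE CASCADE,
  feature_id        INTEGER NOT NULL REFERENCES features(id),
  position          INTEGER NOT NULL,
  location          TEXT NOT NULL DEFAULT '',
  flanking_sequence TEXT NOT NULL DEFAULT '',
  PRIMARY KEY (plant_id, feature_id, position)
);

CREATE TABLE seed_batches (
  system_id           INTEGER PRIMARY KEY AUTOINCREMENT,
  line_id             INTEGER NOT NULL REFERENCES lines(id),
  personal_identifier TEXT NOT NULL,
  generation_label    TEXT NOT NULL DEFAULT '',
  mother_plant        INTEGER REFERENCES plants(id),
  harvest_date        TEXT NOT NULL DEFAULT '',
  storage_place       TEXT NOT NULL DEFAULT '',
  germination_result  TEXT NOT NULL DEFAULT '',
  phenotype_note      TEXT NOT NULL DEFAULT '',
  notebook_ref        TEXT NOT NULL DEFAULT '',
  person_id           INTEGER REFERENCES vocab(id),
  locked              INTEGER NOT NULL DEFAULT 0
);

CREATE TABLE segregation (
  batch_id        INTEGER NOT NULL REFERENCES seed_batches(system_id) ON DELETE CASCADE,
  feature_id      INTEGER NOT NULL REFERENCES features(id),
  observed_counts TEXT NOT NULL DEFAULT '',
  note            TEXT NOT NULL DEFAULT '',
  PRIMARY KEY (batch_id, feature_id)
);

CREATE TABLE attachments (
  id         INTEGER PRIMARY KEY,
  owner_kind TEXT NOT NULL,
  owner_id   INTEGER NOT NULL,
  slot       TEXT NOT NULL DEFAULT '',
  filename   TEXT NOT NULL,
  media_type TEXT NOT NULL DEFAULT 'application/octet-stream',
  content    BLOB NOT NULL
);
"""

#: mutation methods seeded into every fresh database, keyed by category
DEFAULT_METHODS: dict[str, FeatureCategory] = {
    "T-DNA": FeatureCategory.TRANSGENESIS,
    "Transposon": FeatureCategory.TRANSGENESIS,
    "CRISPR": FeatureCategory.ENDOGENOUS,
    "EMS": FeatureCategory.ENDOGENOUS,
    "Gamma irradiation": FeatureCategory.ENDOGENOUS,
    "Natural variant": FeatureCategory.ENDOGENOUS,
}


def hash_password(password: str, salt: str) -> str:
    return hashlib.sha256((salt + password).encode()).hexdigest()


class SeedDatabase:
    """Connection + session (logged-in account) for one laboratory database."""

    def __init__(self, path: str | os.PathLike = ":memory:", login: str = "admin",
                 password: str | None = None):
        self.path = str(path)
        fresh = self.path == ":memory:" or not os.path.exists(self.path) \
            or os.path.getsize(self.path) == 0
        self.conn = sqlite3.connect(self.path)
        self.conn.row_factory = sqlite3.Row
        self.conn.execute("PRAGMA foreign_keys = ON")
        if fresh:
            self.conn.executescript(_SCHEMA)
            salt = secrets.token_hex(8)
            self.conn.execute(
                "INSERT INTO users (login, role, password_hash, salt) VALUES (?,?,?,?)",
                (login, Role.ADMINISTRATOR.value,
                 hash_password(password or "", salt), salt))
            self._seed_defaults()
            self.conn.commit()
        self.login = login
        row = self.conn.execute(
            "SELECT role FROM users WHERE login = ?", (login,)).fetchone()
        if row is None:
            raise NotFoundError(f"no account with login {login!r}")
        self.role = Role(row["role"])

    # -- session / authorization -------------------------------------------

    def require(self, role: Role) -> None:
        if not self.role.allows(role):
            raise AuthorizationError(
                f"{self.login!r} has role {self.role.value}; "
                f"{role.value} required")

    def authenticate(self, login: str, password: str) -> bool:
        row = self.conn.execute(
            "SELECT password_hash, salt FROM users WHERE login = ?",
            (login,)).fetchone()
        if row is None:
            raise NotFoundError(f"no account with login {login!r}")
        return hash_password(password, row["salt"]) == row["password_hash"]

    def switch_user(self, login: str) -> None:
        row = self.conn.execute(
            "SELECT role FROM users WHERE login = ?", (login,)).fetchone()
        if row is None:
            raise NotFoundError(f"no account with login {login!r}")
        self.login, self.role = login, Role(row["role"])

    def create_user(self, login: str, role: Role, password: str = "") -> None:
        """Create a login account (ADMINISTRATOR only)."""
        self.require(Role.ADMINISTRATOR)
        if self.conn.execute("SELECT 1 FROM users WHERE login = ?",
                             (login,)).fetchone():
            raise ConflictError(f"login {login!r} already exists")
        salt = secrets.token_hex(8)
        self.conn.execute(
            "INSERT INTO users (login, role, password_hash, salt) VALUES (?,?,?,?)",
            (login, role.value, hash_password(password, salt), salt))
        self.conn.commit()
        self.audit("create_user", login=login, role=role.value)

    def users(self) -> list[tuple[str, Role]]:
        return [(r["login"], Role(r["role"])) for r in self.conn.execute(
            "SELECT login, role FROM users ORDER BY login")]

    # -- plumbing ----------------------------------------------------------

    def execute(self, sql: str, params: Iterable[Any] = ()) -> sqlite3.Cursor:
        return self.conn.execute(sql, tuple(params))

    def commit(self) -> None:
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "SeedDatabase":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def audit(self, op: str, **details: Any) -> None:
        """Append one line to the write-operation log next to the db file."""
        if self.path == ":memory:":
            return
        entry = {"ts": datetime.datetime.now(datetime.timezone.utc).isoformat(),
                 "login": self.login, "op": op, **details}
        with open(self.path + ".log", "a", encoding="utf-8") as fh:
            fh.write(json.dumps(entry) + "\n")

    # -- bootstrap ---------------------------------------------------------

    def _seed_defaults(self) -> None:
        for value, cat in DEFAULT_METHODS.items():
            self.conn.execute(
                "INSERT INTO vocab (category, value, feature_category, reserved)"
                " VALUES (?,?,?,1)",
                (VocabCategory.MUTATION_METHOD.value, value, cat.value))

    # -- introspection -----------------------------------------------------

    def snapshot(self) -> dict[str, list[tuple]]:
        """Full, deterministic content dump (for equality comparisons)."""
        out: dict[str, list[tuple]] = {}
        tables = [r["name"] for r in self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table'"
            " AND name NOT LIKE 'sqlite_%' ORDER BY name")]
        for t in tables:
            if t == "users":
                # salts are random per account; compare identity + role only
                rows = [tuple(r) for r in self.conn.execute(
                    "SELECT login, role FROM users")]
            else:
                rows = [tuple(r) for r in self.conn.execute(f"SELECT * FROM {t}")]
            out[t] = sorted(rows, key=repr)
        return out
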