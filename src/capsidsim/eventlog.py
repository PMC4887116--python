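"""Reading and writing trajectory event logs and ensemble manifests.

Logs are TSV with a small ``# key=value`` comment header carrying the
protocol metadata needed to replay the trajectory census (subunit count,
time limit, outcome, seed), followed by one row per executed event.
"""

from __future__ import annotations

import json
from pathlib import Path

from .engine import ASSOCIATION, CLOSURE, DISSOCIATION, EventLog, EventRecord

__all__ = [
    "read_event_log",
    "write_event_log",
    "write_manifest",
    "read_manifest",
    "EventLogFormatError",
]

COLUMNS = ("time_s", "kind", "size_i", "size_j", "product_size", "n_assemblies_after")
_KINDS = {ASSOCIATION, DISSOCIATION, CLOSURE}


class EventLogFormatError(ValueError):
    """Malformed or internally inconsistent event-log file."""


def write_event_log(log: EventLog, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_subunits={log.n_subunits}\n")
        fh.write(f"# capsid_size={log.capsid_size}\n")
        fh.write(f"# time_limit={log.time_limit!r}\n")
        fh.write(f"# final_time={log.final_time!r}\n")
        fh.write(f"# completed={int(log.completed)}\n")
        fh.write(f"# seed={'' if log.seed is None else log.seed}\n")
        fh.write("\t".join(COLUMNS) + "\n")
        for r in log.records:
            fh.write(
                f"{r.time!r}\t{r.kind}\t{r.size_i}\t{r.size_j}\t"
                f"{r.product_size}\t{r.n_assemblies_after}\n"
            )


def read_event_log(path) -> EventLog:
    """Parse and validate a log file (strictly non-decreasing event times)."""
    meta: dict[str, str] = {}
    records: list[EventRecord] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields) != COLUMNS:
                    missing = set(COLUMNS) - set(fields)
                    raise EventLogFormatError(
                        f"{path}:{lineno}: bad header; missing column(s) "
                        f"{sorted(missing)}" if missing
                        else f"{path}:{lineno}: bad header {fields}"
                    )
                header_seen = True
                continue
            if len(fields) != len(COLUMNS):
                raise EventLogFormatError(
                    f"{path}:{lineno}: expected {len(COLUMNS)} fields, got {len(fields)}"
                )
            try:
                rec = EventRecord(
                    float(fields[0]), fields[1], int(fields[2]), int(fields[3]),
                    int(fields[4]), int(fields[5]),
                )
            except ValueError as exc:
                raise EventLogFormatError(f"{path}:{lineno}: {exc}") from exc
            if rec.kind not in _KINDS:
                raise EventLogFormatError(
                    f"{path}:{lineno}: unknown event kind {rec.kind!r}"
                )
            records.append(rec)
    if not header_seen:
        raise EventLogFormatError(f"{path}: missing header line")
    for key in ("n_subunits", "capsid_size", "time_limit", "final_time", "completed"):
        if key not in meta:
            raise EventLogFormatError(f"{path}: missing metadata line '# {key}=...'")
    for prev, cur in zip(records, records[1:]):
        if cur.time < prev.time:
            raise EventLogFormatError(
                f"{path}: event times are not non-decreasing "
                f"({cur.time!r} after {prev.time!r})"
            )
    seed = meta.get("seed", "")
    return EventLog(
        n_subunits=int(meta["n_subunits"]),
        capsid_size=int(meta["capsid_size"]),
        time_limit=float(meta["time_limit"]),
        final_time=float(meta["final_time"]),
        completed=bool(int(meta["completed"])),
        seed=int(seed) if seed else None,
        records=records,
    )


def write_manifest(path, *, base_seed: int, seeds: list[int], files: list[str],
                   config: dict) -> None:
    """Record what an ensemble run consisted of (seeds, files, protocol)."""
    doc = {"base_seed": base_seed, "seeds": seeds, "files": files, "config": config}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def read_log_dir(directory) -> list[EventLog]:
    """All ``*.tsv`` event logs in a directory, sorted by filename."""
    paths = sorted(Path(directory).glob("*.tsv"))
    if not paths:
        raise EventLogFormatError(f"no .tsv event logs found in {directory}")
    return [read_event_log(p) for p in paths]
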