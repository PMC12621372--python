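"""The keg archive: partition files bundled with their batch command list.

A keg is a gzip-compressed tar holding ``partitions/<file>`` entries, a
``commands.txt`` with exactly one rendered gapped-extension command per
partition (in plan order), and a ``manifest.tsv`` of plan metadata.  The
keg is the hand-off boundary between the seeding half of the pipeline and
the batched gapped-extension half, so the two can run on different
machines.

Batch execution writes each command's output to its own file and
concatenates them in command order afterwards — never through a pipe — so
the concatenated result is byte-identical for any worker count and command
completion order.  Concatenation deduplicates MAF headers, keeping the
first.
"""

from __future__ import annotations

import concurrent.futures
import subprocess
import tarfile
import tempfile
import time
from dataclasses import dataclass, field
from io import BytesIO
from pathlib import Path
from typing import Callable, Protocol, Sequence

from .maf import concat_maf_texts, render_maf
from .scoring import ScoreModel
from .segio import PathLike, read_segments
from .toyalign import gapped_extend

__all__ = [
    "KegArchive",
    "KegFormatError",
    "BatchError",
    "BatchResult",
    "write_keg",
    "read_keg",
    "run_batch",
    "ToyExtendExecutor",
    "SubprocessExecutor",
]

COMMANDS_NAME = "commands.txt"
MANIFEST_NAME = "manifest.tsv"
PARTITION_DIR = "partitions"


class KegFormatError(ValueError):
    """The archive is structurally invalid (missing or dangling entries)."""


class BatchError(RuntimeError):
    """One or more batch commands failed."""

    def __init__(self, failed: Sequence[int], messages: Sequence[str]):
        self.failed = list(failed)
        super().__init__(
            "batch commands failed at indices "
            + ", ".join(str(i) for i in failed)
            + ": "
            + "; ".join(messages)
        )


@dataclass(slots=True)
class KegArchive:
    """In-memory keg: partition contents, ordered commands, manifest text."""

    partitions: dict[str, bytes]
    commands: list[str]
    manifest: str = ""

    def __post_init__(self) -> None:
        if len(self.commands) != len(self.partitions):
            raise KegFormatError(
                f"{len(self.commands)} commands for {len(self.partitions)} partitions; "
                "expected exactly one command per partition"
            )


def write_keg(
    partition_paths: Sequence[PathLike],
    command_template: str,
    out_path: PathLike,
    manifest: str = "",
) -> Path:
    """Bundle partition files and their rendered commands into a keg.

    ``command_template`` must contain a ``{segments}`` placeholder, which
    is rendered to the archive-relative partition path for each file, in
    the given (plan) order.  Validation happens before anything is
    written.
    """
    if "{segments}" not in command_template:
        raise ValueError("command_template must contain a {segments} placeholder")
    paths = [Path(p) for p in partition_paths]
    for p in paths:
        if not p.is_file():
            raise FileNotFoundError(f"partition file not found: {p}")
    names = [p.name for p in paths]
    if len(set(names)) != len(names):
        raise ValueError("partition file names must be unique within a keg")
    out_path = Path(out_path)
    commands = [
        command_template.format(segments=f"{PARTITION_DIR}/{name}") for name in names
    ]
    with tarfile.open(out_path, "w:gz") as tar:
        for p, name in zip(paths, names):
            tar.add(p, arcname=f"{PARTITION_DIR}/{name}")
        _add_text(tar, COMMANDS_NAME, "".join(c + "\n" for c in commands))
        _add_text(tar, MANIFEST_NAME, manifest)
    return out_path


def _add_text(tar: tarfile.TarFile, name: str, text: str) -> None:
    data = text.encode("utf-8")
    info = tarfile.TarInfo(name)
    info.size = len(data)
    info.mtime = int(time.time())
    tar.addfile(info, BytesIO(data))


def read_keg(path: PathLike) -> KegArchive:
    """Read a keg archive back, preserving entry content and command order."""
    partitions: dict[str, bytes] = {}
    commands: list[str] | None = None
    manifest = ""
    with tarfile.open(path, "r:gz") as tar:
        for member in tar.getmembers():
            if not member.isfile():
                continue
            fh = tar.extractfile(member)
            assert fh is not None
            data = fh.read()
            if member.name == COMMANDS_NAME:
                commands = data.decode("utf-8").splitlines()
            elif member.name == MANIFEST_NAME:
                manifest = data.decode("utf-8")
            elif member.name.startswith(PARTITION_DIR + "/"):
                partitions[member.name.removeprefix(PARTITION_DIR + "/")] = data
    if commands is None:
        raise KegFormatError(f"{path}: archive has no {COMMANDS_NAME}")
    for lineno, cmd in enumerate(commands, start=1):
        referenced = [
            tok.removeprefix(PARTITION_DIR + "/")
            for tok in cmd.split()
            if tok.startswith(PARTITION_DIR + "/")
        ]
        for name in referenced:
            if name not in partitions:
                raise KegFormatError(
                    f"{path}: command line {lineno} references missing partition {name!r}"
                )
    return KegArchive(partitions, commands, manifest)


class Executor(Protocol):
    """Runs one rendered command in ``workdir``; returns its output bytes."""

    def __call__(self, command: str, workdir: Path) -> bytes: ...  # pragma: no cover


@dataclass(slots=True)
class BatchResult:
    """Per-command statuses and outputs plus the concatenated output path."""

    statuses: list[str]
    output_paths: list[Path]
    concatenated_path: Path


@dataclass(slots=True)
class ToyExtendExecutor:
    """Built-in executor running the toy gapped extender on a partition file.

    Commands are expected to end with the archive-relative segment-file
    path (the rendering of ``{segments}``); output is MAF.
    """

    target: str
    query: str
    model: ScoreModel = field(default_factory=ScoreModel)
    target_name: str = "target"
    query_name: str = "query"

    def __call__(self, command: str, workdir: Path) -> bytes:
        tokens = command.split()
        if not tokens:
            raise ValueError("empty command")
        seg_path = workdir / tokens[-1]
        records = read_segments(seg_path)
        alignments = gapped_extend(self.target, self.query, records, self.model)
        text = render_maf(
            alignments, self.target_name, self.query_name, self.target, self.query
        )
        return text.encode("utf-8")


@dataclass(slots=True)
class SubprocessExecutor:
    """Executor that runs commands through the shell, capturing stdout.

    ``nice_increment`` lowers the commands' scheduling priority (useful
    when extension jobs would otherwise starve an upstream producer).
    """

    nice_increment: int | None = None

    def __call__(self, command: str, workdir: Path) -> bytes:
        if self.nice_increment is not None:
            command = f"nice -n {int(self.nice_increment)} {command}"
        proc = subprocess.run(
            command, shell=True, cwd=workdir, capture_output=True, check=False
        )
        if proc.returncode != 0:
            raise RuntimeError(
                f"exit {proc.returncode}: {proc.stderr.decode(errors='replace')[:500]}"
            )
        return proc.stdout


def run_batch(
    archive: KegArchive | PathLike,
    executor: Callable[[str, Path], bytes],
    workers: int = 1,
    workdir: PathLike | None = None,
) -> BatchResult:
    """Execute every command of a keg and concatenate outputs in plan order.

    Commands run on a pool of ``workers`` threads; per-command outputs are
    written to numbered files and concatenated by command index, so the
    concatenated output is independent of the worker count.  If any
    command fails, a :class:`BatchError` lists the failing indices;
    successful partial outputs are kept on disk for inspection.
    """
    if workers < 1:
        raise ValueError(f"workers must be >= 1, got {workers}")
    if not isinstance(archive, KegArchive):
        archive = read_keg(archive)
    if workdir is None:
        workdir = Path(tempfile.mkdtemp(prefix="keg-batch-"))
    else:
        workdir = Path(workdir)
        workdir.mkdir(parents=True, exist_ok=True)
    part_dir = workdir / PARTITION_DIR
    part_dir.mkdir(exist_ok=True)
    for name, data in archive.partitions.items():
        (part_dir / name).write_bytes(data)

    n = len(archive.commands)
    statuses = ["pending"] * n
    outputs: list[bytes | None] = [None] * n
    errors: list[str] = []

    def _run_one(idx: int) -> None:
        try:
            outputs[idx] = executor(archive.commands[idx], workdir)
            statuses[idx] = "ok"
        except Exception as exc:  # noqa: BLE001 - failure is data here
            statuses[idx] = "failed"
            errors.append(f"[{idx}] {exc}")

    if n:
        with concurrent.futures.ThreadPoolExecutor(max_workers=workers) as pool:
            list(pool.map(_run_one, range(n)))

    output_paths: list[Path] = []
    for idx, data in enumerate(outputs):
        out = workdir / f"out_{idx:05d}.maf"
        if data is not None:
            out.write_bytes(data)
        output_paths.append(out)

    failed = [i for i, s in enumerate(statuses) if s != "ok"]
    if failed:
        raise BatchError(failed, errors)

    concatenated = workdir / "combined.maf"
    texts = [p.read_text(encoding="utf-8") for p in output_paths]
    concatenated.write_text(concat_maf_texts(texts), encoding="utf-8")
    return BatchResult(statuses, output_paths, concatenated)
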