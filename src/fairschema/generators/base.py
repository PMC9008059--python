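"""Generator framework: the contract all output generators satisfy.

Every generator is a pure function of the schema (no clock, no randomness,
fixed LF line endings), so two runs on the same bundle produce
byte-identical files and a digest-stable manifest — regeneration "at the
push of a button" is safe to automate and to diff.
"""

from __future__ import annotations

import hashlib
import json
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path, PurePosixPath

from fairschema.model import SemanticSchema, ValidationReport, validate

__all__ = [
    "Generator",
    "GeneratorConfig",
    "GenerationError",
    "ManifestEntry",
    "GenerationManifest",
    "run_generators",
    "registered_targets",
    "register",
]

DEFAULT_NAMESPACE = "https://w3id.org/fair-genomes/resource"
DEFAULT_PROJECT_OID = "2.16.840.1.113883.2.4.3.11.60.120"

_MANIFEST_FILE = ".generated-manifest.json"


class GenerationError(RuntimeError):
    def __init__(self, message: str, report: ValidationReport | None = None):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class GeneratorConfig:
    """Run-wide settings shared by all generators."""

    namespace: str = DEFAULT_NAMESPACE
    project_oid: str = DEFAULT_PROJECT_OID


class Generator(ABC):
    """Base class for all output generators.

    Subclasses implement :meth:`produce`, returning ``(relative path,
    byte content)`` pairs. The base class enforces the shared contract:
    paths relative and unique, output sorted by path, LF line endings.
    """

    target_name: str = ""

    def __init__(self, config: GeneratorConfig | None = None):
        self.config = config or GeneratorConfig()

    @abstractmethod
    def produce(self, schema: SemanticSchema) -> list[tuple[str, bytes]]:
        """Generate all files for this target."""

    def produce_checked(self, schema: SemanticSchema) -> list[tuple[str, bytes]]:
        files = sorted(self.produce(schema), key=lambda f: f[0])
        seen: set[str] = set()
        for path, content in files:
            p = PurePosixPath(path)
            if p.is_absolute() or ".." in p.parts:
                raise GenerationError(f"{self.target_name}: non-relative output path {path!r}")
            if path in seen:
                raise GenerationError(f"{self.target_name}: duplicate output path {path!r}")
            seen.add(path)
            if b"\r" in content:
                raise GenerationError(f"{self.target_name}: {path!r} contains CR line endings")
        return files


_REGISTRY: dict[str, type[Generator]] = {}


def register(cls: type[Generator]) -> type[Generator]:
    """Class decorator adding a generator to the target registry."""
    if not cls.target_name:
        raise ValueError(f"{cls.__name__} lacks a target_name")
    _REGISTRY[cls.target_name] = cls
    return cls


def registered_targets() -> list[str]:
    return sorted(_REGISTRY)


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    size: int
    sha256: str


@dataclass
class GenerationManifest:
    schema_name: str
    schema_version: str
    targets: dict[str, list[ManifestEntry]] = field(default_factory=dict)

    def digest(self) -> str:
        """One digest over the whole manifest; stable across identical runs."""
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def as_dict(self) -> dict:
        return {
            "schema": {"name": self.schema_name, "version": self.schema_version},
            "targets": {
                t: [{"path": e.path, "size": e.size, "sha256": e.sha256} for e in entries]
                for t, entries in self.targets.items()
            },
        }


def run_generators(
    schema: SemanticSchema,
    targets: list[str],
    out_dir: str | Path,
    config: GeneratorConfig | None = None,
) -> GenerationManifest:
    """Run the requested generators and write their files under
    ``out_dir/<target>/``.

    The schema is validated first; an invalid schema is refused with its
    report attached. Files previously written by this function may be
    overwritten on regeneration; a colliding file of foreign origin makes
    the run refuse rather than clobber it (tracked through a manifest file
    inside ``out_dir``).
    """
    if not targets:
        raise GenerationError("no targets requested; pick from: " + ", ".join(registered_targets()))
    unknown = [t for t in targets if t not in _REGISTRY]
    if unknown:
        raise GenerationError(
            f"unknown target(s) {', '.join(unknown)}; registered targets: "
            + ", ".join(registered_targets())
        )
    report = validate(schema)
    if not report.ok:
        raise GenerationError(
            f"schema is invalid ({len(report.errors)} error(s)); refusing to generate",
            report=report,
        )

    config = config or GeneratorConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / _MANIFEST_FILE
    previously_generated: set[str] = set()
    if manifest_path.is_file():
        previously_generated = set(json.loads(manifest_path.read_text(encoding="utf-8")))

    produced: dict[str, list[tuple[str, bytes]]] = {}
    for target in sorted(set(targets)):
        produced[target] = _REGISTRY[target](config).produce_checked(schema)

    # Refuse before writing anything if a foreign file would be clobbered.
    for target, files in produced.items():
        for relpath, _ in files:
            dest = out / target / relpath
            key = f"{target}/{relpath}"
            if dest.exists() and key not in previously_generated:
                raise GenerationError(
                    f"refusing to overwrite {dest}: exists but was not generated by a previous run"
                )

    manifest = GenerationManifest(schema_name=schema.name, schema_version=schema.version)
    generated_keys = set(previously_generated)
    for target, files in produced.items():
        entries = []
        for relpath, content in files:
            dest = out / target / relpath
            dest.parent.mkdir(parents=True, exist_ok=True)
            dest.write_bytes(content)
            entries.append(
                ManifestEntry(relpath, len(content), hashlib.sha256(content).hexdigest())
            )
            generated_keys.add(f"{target}/{relpath}")
        manifest.targets[target] = entries
    manifest_path.write_text(
        json.dumps(sorted(generated_keys), indent=0) + "\n", encoding="utf-8"
    )
    return manifest
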