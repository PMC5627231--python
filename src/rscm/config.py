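"""Flat key-value configuration for parameters and initial conditions.

The config format is plain text, one dotted key per line::

    # comment
    params.f1 = 0.56
    init.xDOC = 61.1

Keys under ``params.`` override :class:`~rscm.core.ModelParameters` fields,
keys under ``init.`` override :class:`~rscm.core.ModelState` fields.  Missing
keys fall back to the packaged defaults (the published batch scenario);
unknown keys raise, naming the offending key.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

from .core import DomainError, ModelParameters, ModelState

__all__ = ["load_config", "dump_config", "parse_config_text"]


def parse_config_text(text: str) -> tuple[ModelParameters, ModelState]:
    """Parse config text into a (parameters, initial state) pair."""
    param_names = {f.name for f in fields(ModelParameters)}
    state_names = {f.name for f in fields(ModelState)}
    params_kw: dict[str, float] = {}
    init_kw: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise DomainError(f"config line {lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        try:
            num = float(value.strip())
        except ValueError as exc:
            raise DomainError(f"config line {lineno}: non-numeric value for {key!r}") from exc
        section, _, field = key.partition(".")
        if section == "params" and field in param_names:
            params_kw[field] = num
        elif section == "init" and field in state_names:
            init_kw[field] = num
        else:
            raise DomainError(f"config line {lineno}: unknown key {key!r}")
    return ModelParameters(**params_kw), ModelState(**init_kw)


def load_config(path: str | Path | None) -> tuple[ModelParameters, ModelState]:
    """Read a config file; ``None`` returns the packaged defaults."""
    if path is None:
        return ModelParameters(), ModelState()
    return parse_config_text(Path(path).read_text())


def dump_config(params: ModelParameters, init: ModelState) -> str:
    """Render a fully-resolved config (every key explicit) as text."""
    lines = [f"params.{f.name} = {getattr(params, f.name)!r}" for f in fields(ModelParameters)]
    lines += [f"init.{f.name} = {getattr(init, f.name)!r}" for f in fields(ModelState)]
    return "\n".join(lines) + "\n"
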