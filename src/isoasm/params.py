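"""Assembly parameters: every algorithmic constant in one validated place."""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

#: Reads shorter than one third of this cannot span three consecutive
#: windows, which the traversal stage requires, so the minimum read
#: length is hard-limited.
HARD_MIN_READ_LEN = 120


class ParamError(ValueError):
    """Raised when an :class:`AssemblyParams` field is out of range."""


@dataclass(frozen=True)
class AssemblyParams:
    """All tunables of the assembly pipeline.

    Fields with non-default semantics:

    min_read_len
        User-facing minimum read length; the network window width is
        derived from it as ``min_read_len // 3``.
    min_isoform_sim
        Hamming-identity threshold used to cluster window fragments
        into network nodes.
    """

    partition_window: int = 100
    partition_identity: float = 0.70
    expansion_sample: int = 12
    min_partition_size: int = 3
    guide_window: int = 100
    guide_identity: float = 0.98
    kmer_length: int = 10
    min_read_len: int = 150
    hard_min_read_len: int = HARD_MIN_READ_LEN
    min_transcript_len: int = 250
    min_isoform_sim: float = 0.96
    edge_min_shared_reads: int = 2
    pair_confirm_fraction: float = 0.30
    rng_seed: int = 0
    max_live_paths: int = 10_000

    @property
    def window_width(self) -> int:
        """Network window width: one third of the minimum read length."""
        return self.min_read_len // 3


def validate(params: AssemblyParams) -> AssemblyParams:
    """Return *params* unchanged if every invariant holds.

    Raises
    ------
    ParamError
        If ``min_read_len`` is below the hard limit, any fraction is
        outside ``(0, 1]``, or any count is non-positive.
    """
    if params.hard_min_read_len != HARD_MIN_READ_LEN:
        raise ParamError(
            f"hard_min_read_len is fixed at {HARD_MIN_READ_LEN}, "
            f"got {params.hard_min_read_len}"
        )
    if params.min_read_len < params.hard_min_read_len:
        raise ParamError(
            f"min_read_len must be >= {params.hard_min_read_len}, "
            f"got {params.min_read_len}"
        )
    for name in ("partition_identity", "guide_identity", "min_isoform_sim",
                 "pair_confirm_fraction"):
        value = getattr(params, name)
        if not 0.0 < value <= 1.0:
            raise ParamError(f"{name} must be in (0, 1], got {value}")
    for name in ("partition_window", "expansion_sample", "min_partition_size",
                 "guide_window", "kmer_length", "min_transcript_len",
                 "edge_min_shared_reads", "max_live_paths"):
        value = getattr(params, name)
        if value < 1:
            raise ParamError(f"{name} must be >= 1, got {value}")
    # 3 * window_width <= min_read_len always holds for floor division;
    # assert the derived width is usable for clustering.
    if params.window_width < params.hard_min_read_len // 3:
        raise ParamError("derived window width too small")
    return params


def load_config(path: str | Path) -> dict[str, object]:
    """Parse a ``key=value`` config file into a field dict.

    Blank lines and ``#`` comments are ignored.  Unknown keys raise
    :class:`ParamError`; values are coerced to the field's type.
    """
    known = {f.name: f.type for f in fields(AssemblyParams)}
    out: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParamError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in known:
            raise ParamError(f"{path}:{lineno}: unknown parameter {key!r}")
        caster = float if "float" in str(known[key]) else int
        try:
            out[key] = caster(value)
        except ValueError as exc:
            raise ParamError(f"{path}:{lineno}: bad value for {key}: {value!r}") from exc
    return out


def make_params(config_file: str | Path | None = None, **overrides) -> AssemblyParams:
    """Build validated params from an optional config file plus overrides.

    Explicit keyword overrides (CLI flags) win over file values.
    """
    values: dict[str, object] = {}
    if config_file is not None:
        values.update(load_config(config_file))
    values.update({k: v for k, v in overrides.items() if v is not None})
    return validate(AssemblyParams(**values))
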