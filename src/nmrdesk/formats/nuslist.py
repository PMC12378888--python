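"""NUS schedule ("nuslist") files: one sampled increment index per line."""

from __future__ import annotations

from ..core import NUSSchedule

__all__ = ["read_nuslist", "write_nuslist"]


def read_nuslist(path: str, full_size: int) -> NUSSchedule:
    """Read a nuslist; lines may carry extra columns, which are ignored.

    The result is sorted and de-duplicated.  Indices at or beyond
    ``full_size`` raise ``schedule exceeds declared grid``.
    """
    increments = []
    with open(path, "r") as fh:
        for line in fh:
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            increments.append(int(fields[0]))
    return NUSSchedule(sampled_increments=tuple(increments),
                       full_size=full_size)


def write_nuslist(schedule: NUSSchedule, path: str) -> None:
    with open(path, "w") as fh:
        for inc in schedule.sampled_increments:
            fh.write(f"{inc}\n")
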