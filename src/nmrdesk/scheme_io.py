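"""Text serialization of processing schemes.

The config mirrors familiar processing-script tokens, one directive per
line inside ``[direct]`` / ``[indirect]`` / ``[global]`` sections::

    [direct]
    SP off=0.5 end=0.95 pow=2
    ZF folds=1
    SOL on
    PS auto
    EXT lo=6.0 hi=10.0
    [indirect]
    EM lb=2.0
    ZF folds=1
    PS p0=90 p1=-180
    [global]
    FIRST_PLANE_ONLY off

``SP`` (sine bell), ``EM`` (exponential), ``GM`` (gaussian) and ``NW`` (no
window) select the window; unknown directives are hard errors.
"""

from __future__ import annotations

from .processing import (AUTO_PHASE, DimensionScheme, PhaseSpec,
                         ProcessingScheme, WindowKind, WindowSpec)

__all__ = ["load_scheme", "dump_scheme", "parse_scheme", "format_scheme"]


class SchemeConfigError(ValueError):
    pass


def _kv(tokens: list[str], directive: str) -> dict:
    out = {}
    for tok in tokens:
        if "=" not in tok:
            raise SchemeConfigError(f"malformed token {tok!r} in {directive}")
        k, v = tok.split("=", 1)
        out[k] = v
    return out


def _flag(value: str) -> bool:
    v = value.lower()
    if v in ("on", "true", "1", "yes"):
        return True
    if v in ("off", "false", "0", "no"):
        return False
    raise SchemeConfigError(f"expected on/off, got {value!r}")


def parse_scheme(text: str) -> ProcessingScheme:
    scheme = ProcessingScheme()
    section: DimensionScheme | None = None
    section_name = ""
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section_name = line.strip("[] ").lower()
            if section_name == "direct":
                section = scheme.direct
            elif section_name == "indirect":
                section = scheme.indirect
            elif section_name == "global":
                section = None
            else:
                raise SchemeConfigError(f"unknown section {section_name!r} "
                                        f"(line {lineno})")
            continue
        tokens = line.split()
        directive, args = tokens[0].upper(), tokens[1:]
        if section_name == "global" or section is None and section_name == "":
            if directive == "FIRST_PLANE_ONLY":
                scheme.first_plane_only = _flag(args[0])
                continue
            raise SchemeConfigError(f"unknown global directive {directive!r} "
                                    f"(line {lineno})")
        assert section is not None
        if directive in ("SP", "EM", "GM", "NW"):
            kv = _kv(args, directive)
            kind = {"SP": WindowKind.SINE_BELL, "EM": WindowKind.EXPONENTIAL,
                    "GM": WindowKind.GAUSSIAN, "NW": WindowKind.NONE}[directive]
            section.window = WindowSpec(
                kind=kind,
                off=float(kv.pop("off", 0.5)),
                end=float(kv.pop("end", 0.95)),
                pow=float(kv.pop("pow", 2.0)),
                lb_hz=float(kv.pop("lb", 0.0)),
                gb=float(kv.pop("gb", 1.0)))
            if kv:
                raise SchemeConfigError(f"unknown keys {sorted(kv)} for "
                                        f"{directive} (line {lineno})")
        elif directive == "ZF":
            section.zero_fill_folds = int(_kv(args, "ZF").get("folds", 1))
        elif directive == "SOL":
            section.solvent_filter = _flag(args[0]) if args else True
        elif directive == "PS":
            if args and args[0].lower() == AUTO_PHASE:
                section.phase = AUTO_PHASE
            else:
                kv = _kv(args, "PS")
                section.phase = PhaseSpec(p0_deg=float(kv.get("p0", 0.0)),
                                          p1_deg=float(kv.get("p1", 0.0)))
        elif directive == "EXT":
            kv = _kv(args, "EXT")
            section.extract_ppm = (float(kv["lo"]), float(kv["hi"]))
        else:
            raise SchemeConfigError(f"unknown directive {directive!r} "
                                    f"(line {lineno})")
    # re-validate cross-field invariants
    return ProcessingScheme(direct=scheme.direct, indirect=scheme.indirect,
                            first_plane_only=scheme.first_plane_only)


def format_scheme(scheme: ProcessingScheme) -> str:
    lines = []
    for name, dim in (("direct", scheme.direct), ("indirect", scheme.indirect)):
        lines.append(f"[{name}]")
        w = dim.window
        if w.kind is WindowKind.SINE_BELL:
            lines.append(f"SP off={w.off} end={w.end} pow={w.pow}")
        elif w.kind is WindowKind.EXPONENTIAL:
            lines.append(f"EM lb={w.lb_hz}")
        elif w.kind is WindowKind.GAUSSIAN:
            lines.append(f"GM lb={w.lb_hz} gb={w.gb}")
        else:
            lines.append("NW")
        lines.append(f"ZF folds={dim.zero_fill_folds}")
        if dim.solvent_filter:
            lines.append("SOL on")
        if dim.phase == AUTO_PHASE:
            lines.append("PS auto")
        else:
            lines.append(f"PS p0={dim.phase.p0_deg} p1={dim.phase.p1_deg}")
        if dim.extract_ppm is not None:
            lines.append(f"EXT lo={dim.extract_ppm[0]} hi={dim.extract_ppm[1]}")
    lines.append("[global]")
    lines.append("FIRST_PLANE_ONLY "
                 + ("on" if scheme.first_plane_only else "off"))
    return "\n".join(lines) + "\n"


def load_scheme(path: str) -> ProcessingScheme:
    with open(path, "r") as fh:
        return parse_scheme(fh.read())


def dump_scheme(scheme: ProcessingScheme, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(format_scheme(scheme))
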