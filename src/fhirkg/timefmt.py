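"""Datetime parsing with per-source declared format patterns.

Every local datetime column declares its format pattern at registration;
all cross-source comparison is done on ISO-8601 renderings at minute
precision.  Two-digit years are resolved against a fixed pivot of 1970
(window 1970–2069), which covers deidentified future-shifted clinical dates.
"""

from __future__ import annotations

from datetime import datetime


class DatetimeParseError(ValueError):
    pass


def parse_datetime(value: str, fmt: str) -> datetime:
    try:
        parsed = datetime.strptime(value.strip(), fmt)
    except ValueError as exc:
        raise DatetimeParseError(f"value {value!r} does not match pattern {fmt!r}") from exc
    if "%y" in fmt and parsed.year < 1970:
        # strptime's two-digit window is 1969-2068; shift to the 1970-2069 pivot
        parsed = parsed.replace(year=parsed.year + 100)
    return parsed


def to_iso_minute(value: str, fmt: str) -> str:
    return parse_datetime(value, fmt).strftime("%Y-%m-%dT%H:%M")


def reformat(value: str, source_format: str, target_format: str) -> str:
    return parse_datetime(value, source_format).strftime(target_format)
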