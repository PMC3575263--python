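"""Minimal ``key=value`` properties files.

Both tools read their defaults from Java-style properties files
(``NDPIsplitter.properties`` for the splitter, ``snapshot-creator.properties``
for the snapshot pipeline).  Only the common subset of the format is
supported: one ``key=value`` pair per line, ``#`` or ``!`` comment lines,
blank lines ignored, whitespace around key and value stripped.  Escapes and
line continuations are not interpreted.
"""

from __future__ import annotations

import os
from pathlib import Path


def load_properties(path: str | os.PathLike) -> dict[str, str]:
    """Read a properties file into an ordered ``{key: value}`` dict."""
    props: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(("#", "!")):
            continue
        if "=" not in line:
            raise ValueError(f"malformed properties line (no '='): {raw!r}")
        key, _, value = line.partition("=")
        props[key.strip()] = value.strip()
    return props


def dump_properties(props: dict[str, str], path: str | os.PathLike) -> None:
    """Write ``props`` as ``key=value`` lines."""
    lines = [f"{k}={v}" for k, v in props.items()]
    Path(path).write_text("\n".join(lines) + "\n")
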