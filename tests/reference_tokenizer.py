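"""Independent character-level reference tokenizer used as a test oracle.

Deliberately implemented with a different strategy from the package's
scanner: the document is processed line by line with an explicit state
machine for semicolon text fields, and each line is consumed with a cursor.
Only (kind, text) pairs are produced; agreement with the package tokenizer
is asserted elsewhere.
"""

from __future__ import annotations

WHITESPACE = " \t"


class RefError(Exception):
    pass


def _classify(word: str) -> tuple[str, str]:
    low = word.lower()
    if low.startswith("data_"):
        return ("DATA_HEADING", word[5:])
    if low == "save_":
        return ("SAVE_END", "")
    if low.startswith("save_"):
        return ("SAVE_HEADING", word[5:])
    if low == "loop_":
        return ("LOOP", "")
    if low in ("stop_", "global_"):
        raise RefError(f"reserved word {word}")
    if word.startswith("_"):
        return ("TAG", word[1:])
    return ("VALUE", word)


def ref_tokenize(text: str) -> list[tuple[str, str]]:
    text = text.replace("\r\n", "\n").replace("\r", "\n")
    lines = text.split("\n")
    out: list[tuple[str, str]] = []
    in_field = False
    field_lines: list[str] = []
    for line in lines:
        if in_field:
            if line.startswith(";"):
                out.append(("VALUE", "\n".join(field_lines)))
                in_field = False
                _scan_line(line[1:], out, allow_field_open=False)
            else:
                field_lines.append(line)
            continue
        if line.startswith(";"):
            in_field = True
            field_lines = [line[1:]]
            continue
        _scan_line(line, out, allow_field_open=False)
    if in_field:
        raise RefError("unterminated text field")
    return out


def _scan_line(line: str, out: list, allow_field_open: bool) -> None:
    pos = 0
    n = len(line)
    while pos < n:
        ch = line[pos]
        if ch in WHITESPACE:
            pos += 1
            continue
        if ch == "#":
            return
        if ch in ("'", '"'):
            end = None
            scan = pos + 1
            while scan < n:
                if line[scan] == ch and (
                    scan + 1 >= n or line[scan + 1] in WHITESPACE
                ):
                    end = scan
                    break
                scan += 1
            if end is None:
                raise RefError("unterminated quote")
            out.append(("VALUE", line[pos + 1 : end]))
            pos = end + 1
            continue
        scan = pos
        while scan < n and line[scan] not in WHITESPACE:
            scan += 1
        out.append(_classify(line[pos:scan]))
        pos = scan
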