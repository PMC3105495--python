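"""Reading and writing the OBO 1.2 flat-file format.

The format is line-oriented ``tag: value`` text.  On every line, an
unescaped ``!`` starts a comment running to the end of the line, an
unescaped ``{...}`` group at the end of the value holds trailing modifiers
(qualifiers), and backslash escapes protect the structural characters
(see :data:`ESCAPE_TABLE`).  Quoted strings carry definition and synonym
text; bracketed lists carry database cross-references.

Parsing is lossless at the document-model level: inline comments,
full-line comments, qualifiers and unknown tags are all captured so that
``parse_obo(serialize_obo(doc))`` reproduces ``doc`` structurally.
Serialization with ``canonical=True`` is byte-deterministic.
"""

from __future__ import annotations

from typing import Optional

from .model import (
    BOOLEAN_TAGS,
    ID_TAGS,
    ClauseValue,
    DbXref,
    DefClause,
    HeaderClause,
    IdSpaceDecl,
    ImportRef,
    LogicalClause,
    LogicalKind,
    OboError,
    OBODocument,
    OBOId,
    RelationshipClause,
    Stanza,
    StanzaKind,
    SubsetDef,
    SynonymClause,
    SynonymScope,
    SynonymTypeDef,
    TagValue,
    canonicalize,
)

__all__ = [
    "parse_obo",
    "serialize_obo",
    "escape_value",
    "unescape_value",
    "parse_def_clause",
    "parse_synonym_clause",
    "parse_relationship_clause",
    "parse_clause_value",
    "parse_id",
    "serialize_clause_value",
    "render_header_value",
    "serialize_header_value",
    "parse_header_value",
    "serialize_xref",
    "parse_xref",
    "COMMENT_TAG",
]

#: pseudo-tag used to preserve full-line ``! ...`` comments
COMMENT_TAG = "!"

# escape character -> decoded character
ESCAPE_TABLE = {
    "n": "\n",
    "t": "\t",
    "\\": "\\",
    '"': '"',
    ":": ":",
    ",": ",",
    "{": "{",
    "}": "}",
    "[": "[",
    "]": "]",
    "!": "!",
}
_REVERSE_ESCAPES = {"\n": "n", "\t": "t"}

_SCOPE_KEYWORDS = {s.name: SynonymScope[s.name] for s in SynonymScope if s.name != "UNSPECIFIED"}
_LOGICAL_TAGS = {
    "intersection_of": LogicalKind.INTERSECTION_OF,
    "union_of": LogicalKind.UNION_OF,
    "disjoint_from": LogicalKind.DISJOINT_FROM,
}


# --------------------------------------------------------------------------
# escapes


def unescape_value(escaped: str) -> str:
    """Decode OBO backslash escapes; raises ``E_BAD_ESCAPE`` on a dangling
    backslash or an unknown escape character."""
    out = []
    i = 0
    n = len(escaped)
    while i < n:
        ch = escaped[i]
        if ch == "\\":
            if i + 1 >= n:
                raise OboError("E_BAD_ESCAPE", f"dangling backslash in {escaped!r}")
            nxt = escaped[i + 1]
            if nxt not in ESCAPE_TABLE:
                raise OboError("E_BAD_ESCAPE", f"unknown escape \\{nxt} in {escaped!r}")
            out.append(ESCAPE_TABLE[nxt])
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def escape_value(raw: str) -> str:
    """Encode every escapable character; exact inverse of
    :func:`unescape_value` on its output."""
    out = []
    for ch in raw:
        if ch in _REVERSE_ESCAPES:
            out.append("\\" + _REVERSE_ESCAPES[ch])
        elif ch in ('"', ":", ",", "{", "}", "[", "]", "!", "\\"):
            out.append("\\" + ch)
        else:
            out.append(ch)
    return "".join(out)


def _esc(raw: str, specials: str) -> str:
    """Context-sensitive escaping: backslash/newline/tab plus *specials*."""
    out = []
    for ch in raw:
        if ch == "\\":
            out.append("\\\\")
        elif ch in _REVERSE_ESCAPES:
            out.append("\\" + _REVERSE_ESCAPES[ch])
        elif ch in specials:
            out.append("\\" + ch)
        else:
            out.append(ch)
    return "".join(out)


def _esc_plain(raw: str) -> str:
    return _esc(raw, "!{")


def _esc_tag(raw: str) -> str:
    return _esc(raw, ":!{")


def _esc_id_part(raw: str) -> str:
    return _esc(raw, ":!{}[],\"")


def _esc_quoted(raw: str) -> str:
    return _esc(raw, '"!{}')


def _esc_xref_id(raw: str) -> str:
    return _esc(raw, '"!{}[],')


def _esc_token(raw: str) -> str:
    return _esc(raw, '"!{}[]')


# --------------------------------------------------------------------------
# low-level scanning over still-escaped text


def _find_unescaped(s: str, chars: str, start: int = 0) -> int:
    i = start
    while i < len(s):
        if s[i] == "\\":
            i += 2
            continue
        if s[i] in chars:
            return i
        i += 1
    return -1


def _split_unescaped(s: str, sep: str) -> list[str]:
    parts = []
    start = 0
    while True:
        i = _find_unescaped(s, sep, start)
        if i < 0:
            parts.append(s[start:])
            return parts
        parts.append(s[start:i])
        start = i + 1


def _split_ws(s: str) -> list[str]:
    """Split on unescaped whitespace runs."""
    tokens = []
    cur = []
    i = 0
    while i < len(s):
        ch = s[i]
        if ch == "\\" and i + 1 < len(s):
            cur.append(s[i : i + 2])
            i += 2
            continue
        if ch in " \t":
            if cur:
                tokens.append("".join(cur))
                cur = []
        else:
            cur.append(ch)
        i += 1
    if cur:
        tokens.append("".join(cur))
    return tokens


def _take_quoted(s: str) -> tuple[str, str]:
    """Consume a leading quoted string; returns (raw inner text, rest)."""
    s = s.lstrip()
    if not s.startswith('"'):
        raise OboError("E_SYNTAX", f"expected quoted string at {s!r}")
    end = _find_unescaped(s, '"', 1)
    if end < 0:
        raise OboError("E_SYNTAX", f"unterminated quote in {s!r}")
    return s[1:end], s[end + 1 :]


# --------------------------------------------------------------------------
# clause payload parsers


def parse_id(raw: str) -> OBOId:
    """Parse an OBO identifier; the first unescaped ``:`` separates the ID
    space from the local part, its absence makes the id flat."""
    raw = raw.strip()
    i = _find_unescaped(raw, ":")
    if i <= 0:
        return OBOId(local=unescape_value(raw))
    return OBOId(idspace=unescape_value(raw[:i]), local=unescape_value(raw[i + 1 :]))


def _render_id(oid: OBOId) -> str:
    if oid.idspace is None:
        return _esc_id_part(oid.local)
    # colons inside the local part are unambiguous (split is at the first)
    local_specials = '!{}[],"'
    return f"{_esc_id_part(oid.idspace)}:{_esc(oid.local, local_specials)}"


def _parse_xref_token(token: str) -> DbXref:
    token = token.strip()
    q = _find_unescaped(token, '"')
    if q < 0:
        return DbXref(id=unescape_value(token))
    ident = token[:q].strip()
    desc, rest = _take_quoted(token[q:])
    if rest.strip():
        raise OboError("E_SYNTAX", f"trailing text after xref description: {rest!r}")
    return DbXref(id=unescape_value(ident), description=unescape_value(desc))


def _parse_xref_list(raw: str) -> tuple[tuple[DbXref, ...], str]:
    raw = raw.lstrip()
    if not raw.startswith("["):
        raise OboError("E_SYNTAX", f"expected '[' at {raw!r}")
    end = _find_unescaped(raw, "]", 1)
    if end < 0:
        raise OboError("E_SYNTAX", f"unterminated xref list in {raw!r}")
    inner = raw[1:end].strip()
    rest = raw[end + 1 :]
    if not inner:
        return (), rest
    xrefs = tuple(_parse_xref_token(t) for t in _split_unescaped(inner, ","))
    return xrefs, rest


def parse_def_clause(raw: str) -> DefClause:
    """``"definition text" [XREF, ...]`` — the bracketed list may be absent."""
    text, rest = _take_quoted(raw)
    rest = rest.strip()
    xrefs: tuple[DbXref, ...] = ()
    if rest:
        xrefs, rest = _parse_xref_list(rest)
        if rest.strip():
            raise OboError("E_SYNTAX", f"trailing text after def xrefs: {rest!r}")
    return DefClause(text=unescape_value(text), xrefs=xrefs)


def parse_synonym_clause(raw: str) -> SynonymClause:
    """``"text" [SCOPE] [TYPE] [xref, ...]`` — scope keyword and synonym-type
    name are optional; scope defaults to UNSPECIFIED."""
    text, rest = _take_quoted(raw)
    scope = SynonymScope.UNSPECIFIED
    type_name: Optional[str] = None
    xrefs: tuple[DbXref, ...] = ()
    rest = rest.strip()
    seen_scope = seen_type = False
    while rest:
        if rest.startswith("["):
            xrefs, rest = _parse_xref_list(rest)
            if rest.strip():
                raise OboError("E_SYNTAX", f"trailing text after synonym xrefs: {rest!r}")
            break
        tokens = _split_ws(rest)
        token, rest = tokens[0], rest[len(tokens[0]) :].strip() if tokens else ""
        word = unescape_value(token)
        if not seen_scope and not seen_type and word in _SCOPE_KEYWORDS:
            scope = _SCOPE_KEYWORDS[word]
            seen_scope = True
        elif not seen_type:
            type_name = word
            seen_type = True
        else:
            raise OboError("E_SYNTAX", f"unexpected token {word!r} in synonym clause")
    return SynonymClause(text=unescape_value(text), scope=scope, type_name=type_name, xrefs=xrefs)


def parse_relationship_clause(raw: str) -> RelationshipClause:
    """``TYPE_ID TARGET_ID`` — exactly two whitespace-separated identifiers."""
    tokens = _split_ws(raw.strip())
    if len(tokens) != 2:
        raise OboError("E_SYNTAX", f"relationship needs 2 ids, got {len(tokens)}: {raw!r}")
    return RelationshipClause(type_id=parse_id(tokens[0]), target_id=parse_id(tokens[1]))


def _parse_logical_clause(tag: str, raw: str) -> LogicalClause:
    kind = _LOGICAL_TAGS[tag]
    tokens = _split_ws(raw.strip())
    if kind is LogicalKind.INTERSECTION_OF and len(tokens) == 2:
        return LogicalClause(kind, operand_relation=parse_id(tokens[0]), operand_class=parse_id(tokens[1]))
    if len(tokens) != 1:
        raise OboError("E_SYNTAX", f"{tag} expects one class id{' or REL CLASS' if kind is LogicalKind.INTERSECTION_OF else ''}: {raw!r}")
    return LogicalClause(kind, operand_class=parse_id(tokens[0]))


def parse_clause_value(tag: str, raw: str) -> ClauseValue:
    """Parse the (still escaped) value text of a stanza clause for *tag*."""
    if tag in BOOLEAN_TAGS:
        word = unescape_value(raw.strip())
        if word == "true":
            return True
        if word == "false":
            return False
        return word  # malformed; flagged by validate_document
    if tag == "def":
        return parse_def_clause(raw)
    if tag == "synonym":
        return parse_synonym_clause(raw)
    if tag == "relationship":
        return parse_relationship_clause(raw)
    if tag in _LOGICAL_TAGS:
        return _parse_logical_clause(tag, raw)
    if tag in ID_TAGS:
        return parse_id(raw)
    return unescape_value(raw.strip())


# --------------------------------------------------------------------------
# header payload parsing / rendering


def parse_header_value(tag: str, raw: str):
    """Parse the escaped value text of a header clause for *tag*.

    Returns (display value, parsed payload or None)."""
    if tag == "idspace":
        tokens = _split_ws(raw.strip())
        if len(tokens) < 2:
            raise OboError("E_BAD_IDSPACE", f"idspace needs a prefix and an IRI: {raw!r}")
        prefix = unescape_value(tokens[0])
        iri = unescape_value(tokens[1])
        desc = None
        rest = raw.strip()
        for t in tokens[:2]:
            rest = rest[rest.index(t) + len(t) :].lstrip()
        if rest:
            desc, trailing = _take_quoted(rest)
            if trailing.strip():
                raise OboError("E_BAD_IDSPACE", f"trailing text in idspace clause: {trailing!r}")
            desc = unescape_value(desc)
        if not prefix or not iri:
            raise OboError("E_BAD_IDSPACE", f"idspace needs a prefix and an IRI: {raw!r}")
        parsed = IdSpaceDecl(prefix=prefix, base_iri=iri, description=desc)
    elif tag == "subsetdef":
        tokens = _split_ws(raw.strip())
        if not tokens:
            raise OboError("E_BAD_HEADER", "empty subsetdef")
        name = unescape_value(tokens[0])
        rest = raw.strip()[len(tokens[0]) :].strip()
        desc = ""
        if rest:
            desc, trailing = _take_quoted(rest)
            if trailing.strip():
                raise OboError("E_BAD_HEADER", f"trailing text in subsetdef: {trailing!r}")
            desc = unescape_value(desc)
        parsed = SubsetDef(name=name, description=desc)
    elif tag == "synonymtypedef":
        tokens = _split_ws(raw.strip())
        if not tokens:
            raise OboError("E_BAD_HEADER", "empty synonymtypedef")
        name = unescape_value(tokens[0])
        rest = raw.strip()[len(tokens[0]) :].strip()
        desc = ""
        scope = None
        if rest:
            desc, trailing = _take_quoted(rest)
            desc = unescape_value(desc)
            trailing = trailing.strip()
            if trailing:
                word = unescape_value(trailing)
                if word not in _SCOPE_KEYWORDS:
                    raise OboError("E_BAD_HEADER", f"bad synonym scope {word!r}")
                scope = _SCOPE_KEYWORDS[word]
        parsed = SynonymTypeDef(name=name, description=desc, default_scope=scope)
    elif tag == "import":
        target = unescape_value(raw.strip())
        parsed = ImportRef(target=target)
    else:
        return unescape_value(raw.strip()), None
    return render_header_value(tag, parsed), parsed


def render_header_value(tag: str, parsed) -> str:
    """Canonical display string for a structured header payload."""
    if isinstance(parsed, IdSpaceDecl):
        s = f"{parsed.prefix} {parsed.base_iri}"
        if parsed.description is not None:
            s += f' "{parsed.description}"'
        return s
    if isinstance(parsed, SubsetDef):
        return f'{parsed.name} "{parsed.description}"'
    if isinstance(parsed, SynonymTypeDef):
        s = f'{parsed.name} "{parsed.description}"'
        if parsed.default_scope is not None:
            s += f" {parsed.default_scope.name}"
        return s
    if isinstance(parsed, ImportRef):
        return parsed.target
    raise TypeError(f"no renderer for {parsed!r}")  # pragma: no cover


def serialize_header_value(clause: HeaderClause) -> str:
    """Escaped OBO text form of a header clause value."""
    p = clause.parsed
    if isinstance(p, IdSpaceDecl):
        s = f"{_esc_token(p.prefix)} {_esc_token(p.base_iri)}"
        if p.description is not None:
            s += f' "{_esc_quoted(p.description)}"'
        return s
    if isinstance(p, SubsetDef):
        return f'{_esc_token(p.name)} "{_esc_quoted(p.description)}"'
    if isinstance(p, SynonymTypeDef):
        s = f'{_esc_token(p.name)} "{_esc_quoted(p.description)}"'
        if p.default_scope is not None:
            s += f" {p.default_scope.name}"
        return s
    if isinstance(p, ImportRef):
        return _esc_plain(p.target)
    return _esc_plain(clause.value)


# --------------------------------------------------------------------------
# line-level machinery


class _Ctx:
    def __init__(self, source_name: str):
        self.source_name = source_name
        self.line_number = 0

    def error(self, exc: OboError) -> OboError:
        return OboError(exc.code, exc.args[0].split(": ", 1)[-1], self.source_name, self.line_number)


def _split_comment(line: str) -> tuple[str, Optional[str]]:
    i = _find_unescaped(line, "!")
    if i < 0:
        return line, None
    return line[:i], line[i + 1 :].strip()


def _split_qualifiers(content: str):
    i = _find_unescaped(content, "{")
    if i < 0:
        return content, ()
    end = _find_unescaped(content, "}", i + 1)
    if end < 0:
        raise OboError("E_SYNTAX", f"unterminated trailing modifier in {content!r}")
    if content[end + 1 :].strip():
        raise OboError("E_SYNTAX", "trailing modifiers must end the line")
    inner = content[i + 1 : end].strip()
    quals = []
    if inner:
        for item in _split_unescaped(inner, ","):
            eq = _find_unescaped(item, "=")
            if eq < 0:
                raise OboError("E_SYNTAX", f"trailing modifier item {item!r} lacks '='")
            quals.append((unescape_value(item[:eq].strip()), unescape_value(item[eq + 1 :].strip())))
    return content[:i], tuple(quals)


# --------------------------------------------------------------------------
# document parsing


def parse_obo(text: str, source_name: str = "<string>") -> OBODocument:
    """Parse a complete OBO 1.2 document.

    Raises :class:`~oboowl.model.OboError` with codes ``E_SYNTAX`` (malformed
    line, with line number), ``E_NO_ID`` (stanza without an id clause) or
    ``E_BAD_STANZA`` (unsupported stanza kind, e.g. ``[Instance]``).
    """
    ctx = _Ctx(source_name)
    doc = OBODocument()
    pending: Optional[dict] = None  # {"kind", "id", "clauses"}

    def close_pending():
        nonlocal pending
        if pending is None:
            return
        if pending["id"] is None:
            raise OboError("E_NO_ID", f"{pending['kind'].value} stanza has no id clause",
                           ctx.source_name, pending["line"])
        doc.stanzas.append(Stanza(pending["kind"], pending["id"], pending["clauses"]))
        pending = None

    for lineno, line in enumerate(text.split("\n"), start=1):
        ctx.line_number = lineno
        line = line.rstrip("\r")
        if not line.strip():
            continue
        try:
            content, comment = _split_comment(line)
            stripped = content.strip()
            if not stripped:
                if comment is not None:
                    clause_like = TagValue(COMMENT_TAG, comment)
                    if pending is None:
                        doc.header.append(HeaderClause(COMMENT_TAG, comment))
                    else:
                        pending["clauses"].append(clause_like)
                continue
            if stripped.startswith("["):
                if not (stripped.startswith("[") and stripped.endswith("]")):
                    raise OboError("E_SYNTAX", f"malformed stanza header {stripped!r}")
                kind_name = stripped[1:-1]
                close_pending()
                if kind_name == "Term":
                    kind = StanzaKind.TERM
                elif kind_name == "Typedef":
                    kind = StanzaKind.TYPEDEF
                else:
                    raise OboError("E_BAD_STANZA", f"unsupported stanza kind [{kind_name}]")
                pending = {"kind": kind, "id": None, "clauses": [], "line": lineno}
                continue
            content2, quals = _split_qualifiers(content)
            colon = _find_unescaped(content2, ":")
            if colon < 0:
                raise OboError("E_SYNTAX", f"missing ':' in {stripped!r}")
            tag = unescape_value(content2[:colon].strip())
            value_raw = content2[colon + 1 :].strip()
            if pending is None:
                value, parsed = parse_header_value(tag, value_raw)
                doc.header.append(HeaderClause(tag, value, parsed))
            else:
                if tag == "id":
                    if pending["id"] is not None:
                        raise OboError("E_SYNTAX", "duplicate id clause in stanza")
                    pending["id"] = parse_id(value_raw)
                else:
                    pending["clauses"].append(
                        TagValue(tag, parse_clause_value(tag, value_raw), quals, comment)
                    )
        except OboError as exc:
            if exc.line:
                raise
            raise ctx.error(exc) from exc
    close_pending()
    return doc


# --------------------------------------------------------------------------
# serialization


def serialize_clause_value(tag: str, value: ClauseValue) -> str:
    """Render a clause value back to its escaped OBO text form."""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, OBOId):
        return _render_id(value)
    if isinstance(value, DefClause):
        return f'"{_esc_quoted(value.text)}" {_render_xrefs(value.xrefs)}'
    if isinstance(value, SynonymClause):
        parts = [f'"{_esc_quoted(value.text)}"']
        if value.scope is not SynonymScope.UNSPECIFIED:
            parts.append(value.scope.name)
        if value.type_name:
            parts.append(_esc_token(value.type_name))
        parts.append(_render_xrefs(value.xrefs))
        return " ".join(parts)
    if isinstance(value, RelationshipClause):
        return f"{_render_id(value.type_id)} {_render_id(value.target_id)}"
    if isinstance(value, LogicalClause):
        if value.operand_relation is not None:
            return f"{_render_id(value.operand_relation)} {_render_id(value.operand_class)}"
        return _render_id(value.operand_class)
    return _esc_plain(str(value))


def serialize_xref(x: DbXref) -> str:
    """Escaped text form of one dbxref (``ID`` or ``ID "description"``)."""
    item = _esc_xref_id(x.id)
    if x.description is not None:
        item += f' "{_esc_quoted(x.description)}"'
    return item


def parse_xref(token: str) -> DbXref:
    """Inverse of :func:`serialize_xref`."""
    return _parse_xref_token(token)


def _render_xrefs(xrefs) -> str:
    return "[" + ", ".join(serialize_xref(x) for x in xrefs) + "]"


def _render_clause_line(clause: TagValue) -> str:
    if clause.tag == COMMENT_TAG:
        return f"! {clause.value}"
    line = f"{_esc_tag(clause.tag)}: {serialize_clause_value(clause.tag, clause.value)}"
    if clause.qualifiers:
        inner = ", ".join(f"{_esc(k, '=,!{}')}={_esc(v, '=,!{}')}" for k, v in clause.qualifiers)
        line += " {" + inner + "}"
    if clause.inline_comment is not None:
        line += f" ! {clause.inline_comment}"
    return line


def serialize_obo(doc: OBODocument, canonical: bool = False) -> str:
    """Serialize a document to OBO 1.2 text (LF line endings, UTF-8 safe).

    With ``canonical=True`` the document is canonicalized first, making the
    output byte-deterministic for structurally equal documents.
    """
    if canonical:
        doc = canonicalize(doc)
    blocks: list[str] = []
    if doc.header:
        lines = []
        for clause in doc.header:
            if clause.tag == COMMENT_TAG:
                lines.append(f"! {clause.value}")
            else:
                lines.append(f"{_esc_tag(clause.tag)}: {serialize_header_value(clause)}")
        blocks.append("\n".join(lines))
    for stanza in doc.stanzas:
        lines = [f"[{stanza.kind.value}]", f"id: {_render_id(stanza.id)}"]
        lines.extend(_render_clause_line(c) for c in stanza.clauses)
        blocks.append("\n".join(lines))
    if not blocks:
        return ""
    return "\n\n".join(blocks) + "\n"
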