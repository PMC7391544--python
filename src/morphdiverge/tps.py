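"""Reader/writer for the TPS landmark file dialect produced by tpsDig2.

A record looks like::

    LM=24
    123.0 456.0
    ...            (24 coordinate lines, whitespace separated)
    IMAGE=fish_001.jpg
    ID=fish_001
    SCALE=0.021

``IMAGE=``, ``ID=`` and ``SCALE=`` trailers are optional and may appear in
any order after the coordinate block. CRLF line endings are tolerated.
Coordinates are Cartesian with y increasing upward; pass ``invert_y=True``
for image-origin files (Procrustes shape is invariant to this, plots are
not).
"""

from __future__ import annotations

from pathlib import Path

from .types import N_LANDMARKS, LandmarkSet, MalformedRecordError


def read_tps(path: str | Path, invert_y: bool = False) -> list[LandmarkSet]:
    """Parse a TPS file into a list of :class:`LandmarkSet`, file order kept.

    Raises :class:`MalformedRecordError` if a record does not declare exactly
    24 landmarks, and a parse error naming the line for non-numeric
    coordinates. SCALE is stored, never pre-multiplied.
    """
    path = Path(path)
    records: list[LandmarkSet] = []
    lines = path.read_text(encoding="utf-8").splitlines()

    i = 0
    n_record = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise MalformedRecordError(
                f"{path.name}:{i + 1}: expected 'LM=' record header, got {line!r}"
            )
        n_record += 1
        try:
            n_lm = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise MalformedRecordError(
                f"{path.name}:{i + 1}: unreadable landmark count in {line!r}"
            ) from exc
        if n_lm != N_LANDMARKS:
            raise MalformedRecordError(
                f"{path.name}: record {n_record} declares LM={n_lm}; "
                f"this digitization scheme requires LM={N_LANDMARKS}"
            )
        i += 1
        coords = []
        for j in range(n_lm):
            if i >= len(lines):
                raise MalformedRecordError(
                    f"{path.name}: record {n_record} truncated after "
                    f"{j} of {n_lm} coordinate lines"
                )
            parts = lines[i].split()
            if len(parts) != 2:
                raise MalformedRecordError(
                    f"{path.name}:{i + 1}: expected 'x y' coordinate line, "
                    f"got {lines[i]!r}"
                )
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise MalformedRecordError(
                    f"{path.name}:{i + 1}: non-numeric coordinate in {lines[i]!r}"
                ) from exc
            i += 1
        # optional trailers until next LM= or EOF
        image = None
        specimen_id = None
        scale = None
        while i < len(lines):
            trailer = lines[i].strip()
            if not trailer:
                i += 1
                continue
            upper = trailer.upper()
            if upper.startswith("LM="):
                break
            if upper.startswith("IMAGE="):
                image = trailer.split("=", 1)[1].strip()
            elif upper.startswith("ID="):
                specimen_id = trailer.split("=", 1)[1].strip()
            elif upper.startswith("SCALE="):
                try:
                    scale = float(trailer.split("=", 1)[1])
                except ValueError as exc:
                    raise MalformedRecordError(
                        f"{path.name}:{i + 1}: non-numeric SCALE in {trailer!r}"
                    ) from exc
            else:
                raise MalformedRecordError(
                    f"{path.name}:{i + 1}: unrecognized line {trailer!r}"
                )
            i += 1
        arr = [(x, -y) for x, y in coords] if invert_y else coords
        records.append(
            LandmarkSet(
                specimen_id=specimen_id or f"specimen_{n_record}",
                coords=arr,
                scale=scale,
                image=image,
            )
        )
    return records


def write_tps(sets: list[LandmarkSet], path: str | Path) -> None:
    """Write landmark sets as TPS; round-trips coordinates at 6 decimals."""
    path = Path(path)
    out: list[str] = []
    for s in sets:
        out.append(f"LM={N_LANDMARKS}")
        for x, y in s.coords:
            out.append(f"{x:.6f} {y:.6f}")
        if s.image is not None:
            out.append(f"IMAGE={s.image}")
        out.append(f"ID={s.specimen_id}")
        if s.scale is not None:
            out.append(f"SCALE={s.scale:.6f}")
    text = "\n".join(out)
    if text:
        text += "\n"
    path.write_text(text, encoding="utf-8")
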