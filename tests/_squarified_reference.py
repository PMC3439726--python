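"""Independent transcription of the published squarified-treemap algorithm.

Recursive, row-by-row, following the original pseudocode: rows are built
along the shorter side of the remaining free rectangle, an item joins the
current row while it does not worsen the row's worst aspect ratio, and a
finished row is laid out before recursing on the rest.  Kept separate from
the package implementation so the two can be compared as independent
routes.
"""

from omicsview.data_io import Rect


def _worst(row, w):
    s = sum(row)
    return max(max((w * w * r) / (s * s), (s * s) / (w * w * r)) for r in row)


def _layoutrow(row, free):
    s = sum(row)
    rects = []
    if free.w >= free.h:  # row along the left (vertical) side
        width = s / free.h
        y = free.y
        for r in row:
            rects.append(Rect(free.x, y, width, r / width))
            y += r / width
        free = Rect(free.x + width, free.y, free.w - width, free.h)
    else:
        height = s / free.w
        x = free.x
        for r in row:
            rects.append(Rect(x, free.y, r / height, height))
            x += r / height
        free = Rect(free.x, free.y + height, free.w, free.h - height)
    return rects, free


def squarified_reference(areas, rect):
    """Tile ``rect`` with the given areas (summing to rect.area), in order."""
    out = []

    def recurse(children, row, free):
        if not children:
            if row:
                rects, free2 = _layoutrow(row, free)
                out.extend(rects)
            return
        c = children[0]
        w = min(free.w, free.h)
        if not row or _worst(row, w) >= _worst(row + [c], w):
            recurse(children[1:], row + [c], free)
        else:
            rects, free2 = _layoutrow(row, free)
            out.extend(rects)
            recurse(children, [], free2)

    recurse(list(areas), [], rect)
    return out
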