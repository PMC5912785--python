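"""Rectangular regions of interest in 0-based pixel coordinates."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Rect:
    """An axis-aligned rectangle: top-left corner (x, y), width w along x,
    height h along y.  Half-open, FIJI-style."""

    x: int
    y: int
    w: int
    h: int

    @property
    def rows(self) -> slice:
        return slice(self.y, self.y + self.h)

    @property
    def cols(self) -> slice:
        return slice(self.x, self.x + self.w)

    @property
    def area(self) -> int:
        return self.w * self.h

    def check_within(self, shape: tuple[int, ...]) -> None:
        ny, nx = shape[-2], shape[-1]
        if self.x < 0 or self.y < 0 or self.x + self.w > nx or self.y + self.h > ny:
            raise ValueError(f"ROI {self} outside image of shape {(ny, nx)}")

    @classmethod
    def centered(cls, cx: float, cy: float, w: int, h: int) -> "Rect":
        return cls(x=int(round(cx - w / 2)), y=int(round(cy - h / 2)), w=w, h=h)
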