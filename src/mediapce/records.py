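"""Document- and video-level record types with JSONL round-tripping.

A :class:`MediaDocument` is one dated media item carrying valence evidence.
Long-form items (newspapers, wire, broadcast transcripts, web blogs) carry
classifier *probabilities* of being anti- or pro-tobacco; short-form items
(tweets, video metadata) carry binary flags.  A :class:`VideoRecord` is one
video with its publish date and daily view stream.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

#: The five-way hand-coding scheme for valence.
CODING_LABELS = ("anti", "pro", "mixed", "not_applicable", "irrelevant")

SourceType = Literal["longform", "twitter", "youtube"]
Valence = Literal["anti", "pro"]


class MediaDocument(BaseModel):
    """One dated text/tweet/video-metadata record with valence evidence."""

    doc_id: str
    source: str
    source_type: SourceType
    date: dt.date
    p_anti: float = Field(ge=0.0, le=1.0)
    p_pro: float = Field(ge=0.0, le=1.0)
    more_than_passing: bool = True
    coder_votes: Optional[dict[str, int]] = None

    @field_validator("coder_votes")
    @classmethod
    def _votes_valid(cls, v: Optional[dict[str, int]]) -> Optional[dict[str, int]]:
        if v is None:
            return v
        for label, count in v.items():
            if label not in CODING_LABELS:
                raise ValueError(f"unknown coding label {label!r}")
            if count < 0:
                raise ValueError("vote counts must be non-negative")
        return v

    @model_validator(mode="after")
    def _short_form_rules(self) -> "MediaDocument":
        if self.source_type in ("twitter", "youtube"):
            if self.p_anti not in (0.0, 1.0) or self.p_pro not in (0.0, 1.0):
                raise ValueError(
                    f"{self.source_type} records carry binary valence flags, "
                    f"got p_anti={self.p_anti}, p_pro={self.p_pro}"
                )
            # Every relevant tweet/video counts as a substantial mention:
            # a tweet is short enough that any tobacco mention dominates it.
            if not self.more_than_passing:
                raise ValueError(
                    f"{self.source_type} records are always more-than-passing"
                )
        return self


class VideoRecord(BaseModel):
    """One video: publish date, valence label, and daily view counts."""

    video_id: str
    publish_date: dt.date
    valence: Literal["anti", "pro", "none"]
    daily_views: dict[dt.date, int] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _views_valid(self) -> "VideoRecord":
        for day, views in self.daily_views.items():
            if views < 0:
                raise ValueError(f"negative view count on {day}")
            if day < self.publish_date:
                raise ValueError(
                    f"views on {day} precede publish date {self.publish_date}"
                )
        return self

    def views_between(self, start: dt.date, end: dt.date) -> int:
        """Total views on days ``start <= d <= end``."""
        return sum(v for d, v in self.daily_views.items() if start <= d <= end)


def write_jsonl(records: Iterable[BaseModel], path: str | Path) -> int:
    """Write records one JSON object per line (ISO-8601 dates). Returns count."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.model_dump(mode="json"), sort_keys=True))
            fh.write("\n")
            n += 1
    return n


def _read_jsonl(path: str | Path, model: type) -> Iterator:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield model.model_validate(json.loads(line))


def read_documents(path: str | Path) -> list[MediaDocument]:
    return list(_read_jsonl(path, MediaDocument))


def read_videos(path: str | Path) -> list[VideoRecord]:
    return list(_read_jsonl(path, VideoRecord))
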