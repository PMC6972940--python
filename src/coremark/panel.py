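"""Primer-panel container and TSV dialect.

A panel row describes one multiplexed amplicon marker: its id
(``chrom_pos`` with a 1-based amplicon start), the amplicon interval on
the reference (stored 0-based half-open), and the forward/reverse
primer sequences (reverse primer given 5'->3' on the opposite strand,
i.e. the reverse complement of the amplicon's 3' end).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PanelMarker:
    marker_id: str
    chrom: str
    start: int  # 0-based amplicon start
    end: int    # half-open amplicon end
    fwd_primer: str
    rev_primer: str
    n_target_variants: int = 0
    status: str = "ok"

    @property
    def amplicon_len(self) -> int:
        return self.end - self.start

    def fwd_window(self) -> tuple[int, int]:
        return (self.start, self.start + len(self.fwd_primer))

    def rev_window(self) -> tuple[int, int]:
        return (self.end - len(self.rev_primer), self.end)


_HEADER = [
    "marker_id", "chrom", "amplicon_start", "amplicon_end",
    "fwd_primer_seq", "rev_primer_seq", "n_target_variants", "status",
]


@dataclass
class PrimerPanel:
    markers: list[PanelMarker] = field(default_factory=list)

    def __post_init__(self):
        seen: dict[str, str] = {}
        for m in self.markers:
            if m.marker_id in seen:
                raise ValueError(f"duplicate marker id {m.marker_id}")
            seen[m.marker_id] = m.fwd_primer
        fwd = [m.fwd_primer for m in self.markers]
        if len(set(fwd)) != len(fwd):
            raise ValueError("forward primers are not unique across the panel")

    def __iter__(self):
        return iter(self.markers)

    def __len__(self):
        return len(self.markers)

    def get(self, marker_id: str) -> PanelMarker:
        for m in self.markers:
            if m.marker_id == marker_id:
                return m
        raise KeyError(marker_id)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(_HEADER) + "\n")
            for m in self.markers:
                fh.write(
                    f"{m.marker_id}\t{m.chrom}\t{m.start + 1}\t{m.end}\t"
                    f"{m.fwd_primer}\t{m.rev_primer}\t{m.n_target_variants}\t{m.status}\n"
                )

    @classmethod
    def read_tsv(cls, path) -> "PrimerPanel":
        markers = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: header.index(name) for name in _HEADER}
            for line in fh:
                cols = line.rstrip("\n").split("\t")
                if not cols or cols == [""]:
                    continue
                markers.append(
                    PanelMarker(
                        marker_id=cols[idx["marker_id"]],
                        chrom=cols[idx["chrom"]],
                        start=int(cols[idx["amplicon_start"]]) - 1,
                        end=int(cols[idx["amplicon_end"]]),
                        fwd_primer=cols[idx["fwd_primer_seq"]],
                        rev_primer=cols[idx["rev_primer_seq"]],
                        n_target_variants=int(cols[idx["n_target_variants"]]),
                        status=cols[idx["status"]],
                    )
                )
        return cls(markers)
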