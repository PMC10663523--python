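"""Readers and writers for the on-disk formats.

Conformer libraries travel as multi-model PDB files (one MODEL per
conformer, reporters as single atoms addressed by residue number + atom
name); PRE tables as CSV with raw intensity/noise columns (ratios and
errors are always recomputed on load); profiles as TSV; summaries as JSON
embedding the resolved configuration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

from .deuterium import ExtensionProfile, OrderProfile, SplittingTable
from .ensembles import PopulationSummary
from .geometry import Conformer, G_DOMAIN, N_HELIX, PMFSurface

__all__ = [
    "read_conformer_library",
    "write_conformer_library",
    "read_pre_table",
    "write_pre_table",
    "read_splitting_table",
    "write_splitting_table",
    "write_pmf_tsv",
    "write_order_profile_tsv",
    "write_extension_tsv",
    "write_population_json",
]


class IOFormatError(ValueError):
    pass


def _reporter_id(resseq: int, atom: str) -> str:
    return f"{resseq}-{atom}"


def write_conformer_library(path: str | Path, conformers: Sequence[Conformer]) -> None:
    """Write conformers as a multi-model PDB (one reporter atom per residue)."""
    st = gemmi.Structure()
    st.name = "conformer-library"
    for k, cf in enumerate(conformers, start=1):
        model = gemmi.Model(k)
        chain = gemmi.Chain("A")
        for rid, xyz in cf.reporter_table.items():
            resseq_s, atom_name = rid.split("-", 1)
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(resseq_s), " ")
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    Path(path).write_text(st.make_pdb_string())


def read_conformer_library(
    path: str | Path,
    reporter_selection: Sequence[tuple[int, str]] | None = None,
    g_domain_residue_range: tuple[int, int] = (17, 181),
) -> list[Conformer]:
    """One Conformer per PDB MODEL; reporters selected by (residue, atom name).

    Roles are derived from the G-domain residue range (inside -> g_domain,
    outside -> n_helix).  A model missing a selected atom is an error that
    names the model index.
    """
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"no such file: {path}")
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise IOFormatError(f"{path}: no MODEL records")
    wanted = (
        {(int(r), a) for r, a in reporter_selection} if reporter_selection else None
    )
    conformers: list[Conformer] = []
    lo, hi = g_domain_residue_range
    for m_idx, model in enumerate(st, start=1):
        table: dict[str, np.ndarray] = {}
        roles: dict[str, str] = {}
        for chain in model:
            for res in chain:
                for atom in res:
                    key = (res.seqid.num, atom.name)
                    if wanted is not None and key not in wanted:
                        continue
                    rid = _reporter_id(*key)
                    table[rid] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    roles[rid] = G_DOMAIN if lo <= res.seqid.num <= hi else N_HELIX
        if wanted is not None:
            missing = wanted - {(int(r.split("-", 1)[0]), r.split("-", 1)[1]) for r in table}
            if missing:
                raise IOFormatError(
                    f"{path}: model {m_idx} is missing selected atoms {sorted(missing)}"
                )
        if not table:
            raise IOFormatError(f"{path}: model {m_idx} has no reporter atoms")
        conformers.append(
            Conformer(
                id=f"model{m_idx}",
                reporter_table=table,
                reporter_roles=roles,
                g_domain_residue_range=g_domain_residue_range,
            )
        )
    return conformers


PRE_COLUMNS = ["reporter_id", "residue", "atom", "I_para", "I_dia", "sn_para", "sn_dia"]


def read_pre_table(path: str | Path):
    """Load a PRE measurement CSV; ratios and errors are computed, never read."""
    from .pre import PREMeasurement, PREModelError

    df = pd.read_csv(path)
    missing = [col for col in PRE_COLUMNS if col not in df.columns]
    if missing:
        raise IOFormatError(f"{path}: missing columns {missing}")
    try:
        return PREMeasurement(df[PRE_COLUMNS])
    except PREModelError as exc:
        raise IOFormatError(f"{path}: {exc}") from None


def write_pre_table(path: str | Path, measurement) -> None:
    measurement.table[PRE_COLUMNS].to_csv(path, index=False)


def read_splitting_table(path: str | Path) -> SplittingTable:
    df = pd.read_csv(path)
    for col in ("carbon_index", "splitting_khz", "group"):
        if col not in df.columns:
            raise IOFormatError(f"{path}: missing column {col!r}")
    return SplittingTable(
        df["carbon_index"].to_numpy(), df["splitting_khz"].to_numpy(), df["group"].tolist()
    )


def write_splitting_table(path: str | Path, table: SplittingTable) -> None:
    table.to_frame().to_csv(path, index=False)


def write_pmf_tsv(path: str | Path, surface: PMFSurface) -> None:
    """PMF as TSV rows (bin edges, count, free energy; empty bins marked)."""
    rows = []
    nb, ng = surface.counts.shape
    for i in range(nb):
        for j in range(ng):
            count = surface.counts[i, j]
            f = surface.free_energy[i, j]
            rows.append(
                {
                    "beta_low": surface.beta_bin_edges[i],
                    "beta_high": surface.beta_bin_edges[i + 1],
                    "gamma_low": surface.gamma_bin_edges[j],
                    "gamma_high": surface.gamma_bin_edges[j + 1],
                    "count": int(count),
                    "free_energy_kcal_mol": "unvisited" if count == 0 else f"{f:.6f}",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_order_profile_tsv(path: str | Path, profile: OrderProfile) -> None:
    pd.DataFrame({"carbon_index": profile.carbons, "s_cd_abs": profile.s_cd}).to_csv(
        path, sep="\t", index=False
    )


def write_extension_tsv(path: str | Path, ext: ExtensionProfile) -> None:
    # origin convention: terminal CH3 at 0
    pd.DataFrame(
        {
            "carbon_index": ext.carbons,
            "cumulative_from_ch3_A": ext.cumulative_A,
            "segment_travel_A": ext.travel_A,
            "sub_eighth_fallback": ext.sub_eighth,
        }
    ).to_csv(path, sep="\t", index=False)


def write_population_json(
    path: str | Path, summary: PopulationSummary, config: dict | None = None
) -> None:
    """Population summary as JSON, embedding the resolved run configuration."""
    payload = {
        "states": summary.states,
        "mean_percent": summary.mean_percent,
        "sd_percent": summary.sd_percent,
        "ensemble_size": summary.ensemble_size,
        "com_mean_A": summary.com_mean,
        "chi2_per_repeat": summary.chi2_per_repeat.tolist(),
        "per_repeat_fractions": {
            s: summary.per_repeat_fractions[s].tolist() for s in summary.states
        },
        "config": config or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
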