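"""Taxon catalogue: group/flag logic behind every denominator choice.

The Pollen Sum (PS) — the denominator of every percentage in a pollen
diagram — includes all seed-plant pollen and excludes fern and bryophyte
spores, algae and non-pollen palynomorphs (NPP).  Which taxa count as
arboreal, as Poaceae, as cereal-type, as coprophilous fungi or as ancestors
of cultivated trees is likewise a property of the taxon, not of the sample,
so all of it lives here.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import pandas as pd

from .errors import TableValidationError

GROUPS = frozenset({"tree_shrub", "herb", "fern", "bryophyte", "alga", "npp"})
EDIBLE_ORGANS = frozenset({"vegetable", "seed", "fruit", "other", "none"})
LIFE_FORMS = frozenset({"grass_herb", "tree", "none"})

#: groups whose members can never enter the Pollen Sum
OUT_OF_SUM_GROUPS = frozenset({"fern", "bryophyte", "alga", "npp"})

FLAG_COLUMNS = (
    "in_pollen_sum",
    "arboreal",
    "is_poaceae",
    "is_cereal_type",
    "is_coprophilous_fungus",
    "is_cultivated_tree_ancestor",
    "edible",
)

COLUMNS = ("group",) + FLAG_COLUMNS + ("edible_organ", "life_form")


class TaxonCatalogue:
    """Per-taxon group and flag assignments.

    Parameters
    ----------
    table:
        DataFrame indexed by taxon name with columns ``group``,
        ``in_pollen_sum``, ``arboreal``, ``is_poaceae``, ``is_cereal_type``,
        ``is_coprophilous_fungus``, ``is_cultivated_tree_ancestor``,
        ``edible``, ``edible_organ``, ``life_form``.

    Lookups are case-insensitive; the original spelling is preserved.
    Construction enforces the flag invariants (PS excludes ferns,
    bryophytes, algae and NPP; cereal-type implies Poaceae; arboreal implies
    tree/shrub; coprophilous implies NPP).
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        missing = [c for c in COLUMNS if c not in table.columns]
        if missing:
            raise TableValidationError(f"catalogue missing columns {missing}")
        if table.index.duplicated().any():
            dupes = table.index[table.index.duplicated()].tolist()
            raise TableValidationError(f"duplicate taxa in catalogue: {dupes}")
        for col in FLAG_COLUMNS:
            table[col] = table[col].astype(bool)
        self._validate(table)
        table.index.name = "taxon"
        self._table = table[list(COLUMNS)]
        self._lower = {str(n).lower(): n for n in table.index}

    @staticmethod
    def _validate(t: pd.DataFrame) -> None:
        for name, row in t.iterrows():
            if row["group"] not in GROUPS:
                raise TableValidationError(
                    f"unknown group {row['group']!r}", row=name, column="group"
                )
            if row["edible_organ"] not in EDIBLE_ORGANS:
                raise TableValidationError(
                    f"unknown edible_organ {row['edible_organ']!r}",
                    row=name, column="edible_organ",
                )
            if row["life_form"] not in LIFE_FORMS:
                raise TableValidationError(
                    f"unknown life_form {row['life_form']!r}",
                    row=name, column="life_form",
                )
            if row["group"] in OUT_OF_SUM_GROUPS and row["in_pollen_sum"]:
                raise TableValidationError(
                    "spores, algae and NPP cannot enter the Pollen Sum",
                    row=name, column="in_pollen_sum",
                )
            if row["is_cereal_type"] and not row["is_poaceae"]:
                raise TableValidationError(
                    "cereal-type implies Poaceae", row=name, column="is_cereal_type"
                )
            if row["arboreal"] and row["group"] != "tree_shrub":
                raise TableValidationError(
                    "arboreal taxa must be trees or shrubs",
                    row=name, column="arboreal",
                )
            if row["is_coprophilous_fungus"] and row["group"] != "npp":
                raise TableValidationError(
                    "coprophilous fungi are NPP", row=name,
                    column="is_coprophilous_fungus",
                )

    # -- access ----------------------------------------------------------
    @property
    def table(self) -> pd.DataFrame:
        return self._table.copy()

    @property
    def taxa(self) -> pd.Index:
        return self._table.index

    def __contains__(self, name: str) -> bool:
        return str(name).lower() in self._lower

    def __len__(self) -> int:
        return len(self._table)

    def canonical_name(self, name: str) -> str:
        try:
            return self._lower[str(name).lower()]
        except KeyError:
            raise KeyError(f"taxon {name!r} not in catalogue") from None

    def lookup(self, name: str) -> pd.Series:
        """Return the flag row for ``name`` (case-insensitive)."""
        return self._table.loc[self.canonical_name(name)]

    def taxa_where(self, column: str) -> list[str]:
        """Names of taxa whose boolean ``column`` is true."""
        return self._table.index[self._table[column].astype(bool)].tolist()

    # -- modification ----------------------------------------------------
    def merge(self, overrides: pd.DataFrame | "TaxonCatalogue") -> "TaxonCatalogue":
        """Merge user overrides by taxon name, case-insensitively.

        Rows for known taxa replace the existing flags (each changed flag is
        reported through the warning channel); rows for new taxa are
        appended.  Returns a new, re-validated catalogue.
        """
        if isinstance(overrides, TaxonCatalogue):
            overrides = overrides.table
        base = self._table.copy()
        for name, row in overrides.iterrows():
            if name in self:
                canon = self.canonical_name(name)
                changed = [
                    c for c in COLUMNS
                    if c in row.index and base.at[canon, c] != row[c]
                ]
                for c in row.index.intersection(COLUMNS):
                    base.at[canon, c] = row[c]
                if changed:
                    warnings.warn(
                        f"catalogue override for {canon!r} changed {changed}",
                        stacklevel=2,
                    )
            else:
                for c in COLUMNS:
                    if c not in row.index:
                        raise TableValidationError(
                            f"new taxon {name!r} must define all columns",
                            row=name, column=c,
                        )
                base.loc[name] = row[list(COLUMNS)]
        return TaxonCatalogue(base)

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, sep: str = ",") -> "TaxonCatalogue":
        df = pd.read_csv(path, sep=sep, index_col=0)
        for col in FLAG_COLUMNS:
            if col in df.columns and df[col].dtype == object:
                df[col] = df[col].map(
                    {"true": True, "false": False, "True": True, "False": False}
                ).astype(bool)
        return cls(df)

    def to_csv(self, path, sep: str = ",") -> None:
        out = self._table.copy()
        for col in FLAG_COLUMNS:
            out[col] = out[col].map({True: "true", False: "false"})
        out.to_csv(path, sep=sep, index_label="taxon")


def _row(group, *, in_ps=None, arboreal=False, poaceae=False, cereal=False,
         copro=False, cult_tree=False, edible=False, organ="none",
         life_form=None):
    if in_ps is None:
        in_ps = group not in OUT_OF_SUM_GROUPS
    if life_form is None:
        life_form = {"tree_shrub": "tree", "herb": "grass_herb"}.get(group, "none")
    return dict(
        group=group, in_pollen_sum=in_ps, arboreal=arboreal,
        is_poaceae=poaceae, is_cereal_type=cereal,
        is_coprophilous_fungus=copro, is_cultivated_tree_ancestor=cult_tree,
        edible=edible, edible_organ=organ, life_form=life_form,
    )


def default_catalogue() -> TaxonCatalogue:
    """Catalogue pre-populated for a SW-Anatolian steppe-lake assemblage.

    Covers the dominant steppic herbs, the conifer/broadleaf arboreal set,
    the riverine and relictual trees, the cultivated-tree ancestors (Olea,
    Juglans, Castanea, Corylus, Prunus), the cereal-type Poaceae
    (Cerealia-type, Secale), the coprophilous fungi (Sporormiella,
    Podospora, Delitschia, Sordaria, Valsaria variospora) and the main
    out-of-sum palynomorph groups.  Edibility flags and organs are
    illustrative defaults; they are interpretive and meant to be overridden
    via :meth:`TaxonCatalogue.merge` for any real application.
    """
    t = {}
    # arboreal pollen (AP)
    for name in ("Pinus", "Abies", "Cedrus", "Picea", "Cupressaceae",
                 "Quercus deciduous", "Quercus evergreen", "Alnus", "Salix",
                 "Populus", "Tamarix", "Platanus", "Carya", "Liquidambar",
                 "Parrotia", "Pterocarya", "Tsuga", "Zelkova", "Taxodiaceae"):
        t[name] = _row("tree_shrub", arboreal=True)
    for name, organ in (("Olea", "fruit"), ("Juglans", "seed"),
                        ("Castanea", "seed"), ("Corylus", "seed"),
                        ("Prunus", "fruit")):
        t[name] = _row("tree_shrub", arboreal=True, cult_tree=True,
                       edible=True, organ=organ)
    t["Hippophae"] = _row("tree_shrub", arboreal=True, edible=True,
                          organ="fruit")
    t["Ephedra"] = _row("tree_shrub", arboreal=True, edible=True,
                        organ="other")
    t["Fagaceae"] = _row("tree_shrub", arboreal=True, edible=True,
                         organ="seed")
    # herbs
    t["Poaceae"] = _row("herb", poaceae=True, edible=True, organ="seed")
    t["Cerealia-type"] = _row("herb", poaceae=True, cereal=True,
                              edible=True, organ="seed")
    t["Secale"] = _row("herb", poaceae=True, cereal=True, edible=True,
                       organ="seed")
    for name in ("Artemisia", "Convolvulus", "Calystegia", "Linum"):
        t[name] = _row("herb")
    t["Chenopodiaceae"] = _row("herb", edible=True, organ="vegetable")
    t["Plantago"] = _row("herb", edible=True, organ="vegetable")
    t["Compositae"] = _row("herb", edible=True, organ="vegetable")
    # out-of-sum palynomorphs
    t["Filicophyta"] = _row("fern")
    t["Bryophyta"] = _row("bryophyte")
    t["Botryococcus"] = _row("alga")
    t["Chrysophyceae"] = _row("alga")
    for name in ("Sporormiella", "Podospora", "Delitschia", "Sordaria",
                 "Valsaria variospora"):
        t[name] = _row("npp", copro=True)
    t["Glomus"] = _row("npp")
    return TaxonCatalogue(pd.DataFrame.from_dict(t, orient="index"))


def edible_summary(
    catalogue: TaxonCatalogue, observed_taxa: Iterable[str]
) -> dict:
    """Summarise the edible fraction of an observed plant assemblage.

    ``edible_fraction`` is 100 x (observed edible taxa) / (observed plant
    taxa); NPP and algae never enter the denominator.  The grass/tree
    fractions partition the edible set by life form, and organ fractions
    are computed over edible taxa with a recorded organ.
    """
    observed = list(dict.fromkeys(observed_taxa))
    if not observed:
        raise TableValidationError("observed taxon set is empty")
    rows = [catalogue.lookup(n) for n in observed]
    plants = [r for r in rows if r["group"] not in ("npp", "alga")]
    if not plants:
        raise TableValidationError("no plant taxa among observed set")
    edible = [r for r in plants if r["edible"]]
    n_ed = len(edible)
    out: dict = {
        "edible_fraction": 100.0 * n_ed / len(plants),
        "grass_fraction_of_edible": 0.0,
        "tree_fraction_of_edible": 0.0,
        "organ_fractions": {},
    }
    if n_ed == 0:
        return out
    by_form = [r["life_form"] for r in edible]
    out["grass_fraction_of_edible"] = 100.0 * by_form.count("grass_herb") / n_ed
    out["tree_fraction_of_edible"] = 100.0 * by_form.count("tree") / n_ed
    organs = [r["edible_organ"] for r in edible if r["edible_organ"] != "none"]
    if organs:
        for organ in sorted(set(organs)):
            out["organ_fractions"][organ] = 100.0 * organs.count(organ) / len(organs)
    return out
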