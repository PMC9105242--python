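# Reference compositions of the simulated terpenoid / polymer aqueous
# solutions.  Labels: car/thy/ter/cym/mix are pure terpenoid solutions;
# hbpei*/hpg* are polymer-containing systems (the suffix encodes the
# polymer:carvacrol molar ratio; *_mix systems add the minor terpenoids).
# HBPEI chains are partially protonated (+14 e each) and accompanied by
# chloride counterions; HPG is neutral.  gamma-terpinene is tabulated with
# 22 atoms/molecule in the pure-solution series and 26 in the polymer
# series; both values are kept as tabulated (see package docs).

car:
  species:
    - {name: carvacrol, role: terpenoid, molecules: 213, atoms_per_molecule: 25}
    - {name: water, role: water, molecules: 9403, atoms_per_molecule: 3}

thy:
  species:
    - {name: thymol, role: terpenoid, molecules: 209, atoms_per_molecule: 25}
    - {name: water, role: water, molecules: 8526, atoms_per_molecule: 3}

ter:
  species:
    - {name: gamma-terpinene, role: terpenoid, molecules: 245, atoms_per_molecule: 22}
    - {name: water, role: water, molecules: 8207, atoms_per_molecule: 3}

cym:
  species:
    - {name: p-cymene, role: terpenoid, molecules: 243, atoms_per_molecule: 24}
    - {name: water, role: water, molecules: 8279, atoms_per_molecule: 3}

mix:
  species:
    - {name: carvacrol, role: terpenoid, molecules: 1704, atoms_per_molecule: 25}
    - {name: gamma-terpinene, role: terpenoid, molecules: 144, atoms_per_molecule: 22}
    - {name: p-cymene, role: terpenoid, molecules: 168, atoms_per_molecule: 24}
    - {name: thymol, role: terpenoid, molecules: 64, atoms_per_molecule: 25}
    - {name: water, role: water, molecules: 75224, atoms_per_molecule: 3}

hbpei8_7:
  species:
    - {name: HBPEI, role: polymer, molecules: 8, atoms_per_molecule: 355, charge: 14}
    - {name: carvacrol, role: terpenoid, molecules: 56, atoms_per_molecule: 25}
    - {name: water, role: water, molecules: 34040, atoms_per_molecule: 3}
    - {name: Cl, role: ion, molecules: 112, atoms_per_molecule: 1, charge: -1}

hbpei8_14:
  species:
    - {name: HBPEI, role: polymer, molecules: 8, atoms_per_molecule: 355, charge: 14}
    - {name: carvacrol, role: terpenoid, molecules: 112, atoms_per_molecule: 25}
    - {name: water, role: water, molecules: 34040, atoms_per_molecule: 3}
    - {name: Cl, role: ion, molecules: 112, atoms_per_molecule: 1, charge: -1}

hbpei8_21:
  species:
    - {name: HBPEI, role: polymer, molecules: 8, atoms_per_molecule: 355, charge: 14}
    - {name: carvacrol, role: terpenoid, molecules: 168, atoms_per_molecule: 25}
    - {name: water, role: water, molecules: 34040, atoms_per_molecule: 3}
    - {name: Cl, role: ion, molecules: 112, atoms_per_molecule: 1, charge: -1}

hbpei27_7:
  species:
    - {name: HBPEI, role: polymer, molecules: 27, atoms_per_molecule: 355, charge: 14}
    - {name: carvacrol, role: terpenoid, molecules: 189, atoms_per_molecule: 25}
    - {name: water, role: water, molecules: 114885, atoms_per_molecule: 3}
    - {name: Cl, role: ion, molecules: 378, atoms_per_molecule: 1, charge: -1}

hbpei27_mix:
  species:
    - {name: HBPEI, role: polymer, molecules: 27, atoms_per_molecule: 355, charge: 14}
    - {name: carvacrol, role: terpenoid, molecules: 189, atoms_per_molecule: 25}
    - {name: p-cymene, role: terpenoid, molecules: 18, atoms_per_molecule: 24}
    - {name: gamma-terpinene, role: terpenoid, molecules: 15, atoms_per_molecule: 26}
    - {name: thymol, role: terpenoid, molecules: 7, atoms_per_molecule: 25}
    - {name: water, role: water, molecules: 114885, atoms_per_molecule: 3}
    - {name: Cl, role: ion, molecules: 378, atoms_per_molecule: 1, charge: -1}

hpg8_10:
  species:
    - {name: HPG, role: polymer, molecules: 8, atoms_per_molecule: 210}
    - {name: carvacrol, role: terpenoid, molecules: 80, atoms_per_molecule: 25}
    - {name: water, role: water, molecules: 17752, atoms_per_molecule: 3}

hpg8_20:
  species:
    - {name: HPG, role: polymer, molecules: 8, atoms_per_molecule: 210}
    - {name: carvacrol, role: terpenoid, molecules: 160, atoms_per_molecule: 25}
    - {name: water, role: water, molecules: 17752, atoms_per_molecule: 3}

hpg8_30:
  species:
    - {name: HPG, role: polymer, molecules: 8, atoms_per_molecule: 210}
    - {name: carvacrol, role: terpenoid, molecules: 240, atoms_per_molecule: 25}
    - {name: water, role: water, molecules: 17752, atoms_per_molecule: 3}

hpg27_10:
  species:
    - {name: HPG, role: polymer, molecules: 27, atoms_per_molecule: 210}
    - {name: carvacrol, role: terpenoid, molecules: 270, atoms_per_molecule: 25}
    - {name: water, role: water, molecules: 59913, atoms_per_molecule: 3}

hpg27_mix:
  species:
    - {name: HPG, role: polymer, molecules: 27, atoms_per_molecule: 210}
    - {name: carvacrol, role: terpenoid, molecules: 270, atoms_per_molecule: 25}
    - {name: p-cymene, role: terpenoid, molecules: 26, atoms_per_molecule: 24}
    - {name: gamma-terpinene, role: terpenoid, molecules: 22, atoms_per_molecule: 26}
    - {name: thymol, role: terpenoid, molecules: 10, atoms_per_molecule: 25}
    - {name: water, role: water, molecules: 59913, atoms_per_molecule: 3}
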