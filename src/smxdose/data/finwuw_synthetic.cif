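# Synthetic stand-in for the deposited structure of
# catena-bis(mu2-glycyl-histidinato-N,N',O)-nickel(II) heptahydrate
# (CSD refcode FINWUW, CCDC 1901775).  The deposited CIF is not
# redistributed here; this file reconstructs the composition and packing
# from published summary characteristics of the compound: the formula
# Ni(C8H11N4O3)2.7H2O with one formula unit per asymmetric unit, and a
# cell volume fixed by the reported hydrate volume fraction (seven waters
# occupying 19.7% of the cell under the 18 A^3 per non-hydrogen-atom
# packing rule, i.e. V/Z = 7*18/0.197 = 639.6 A^3).  Cell edges and the
# monoclinic angle are plausible but synthetic; only the volume, formula,
# Z and derived density are meaningful.
data_FINWUW_synthetic
_chemical_name_systematic
 'catena-bis(mu!2$-glycyl-histidinato-N,N',O)-nickel(ii) heptahydrate (synthetic reference)'
_chemical_formula_moiety         'C16 H22 N8 Ni O6, 7(H2 O)'
_chemical_formula_sum            'C16 H36 N8 Ni O13'
_chemical_formula_weight         607.20
_space_group_crystal_system      monoclinic
_space_group_name_H-M_alt        'P 1 21 1'
_cell_length_a                   9.6657
_cell_length_b                   11.0000
_cell_length_c                   12.3000
_cell_angle_alpha                90
_cell_angle_beta                 102.00
_cell_angle_gamma                90
_cell_volume                     1279.19
_cell_formula_units_Z            2
_exptl_crystal_density_diffrn    1.576
_exptl_crystal_description       rod
_exptl_crystal_colour            'pale lilac'
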