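# Per-species sample sizes and measurement summaries packaged with transleaf.
# Transcribed from the published per-species attribute summary (n_attr,
# DBH and live-crown-ratio mean/SD) and from the published per-species
# cross-validation table (n_cv). The two printed sample-size columns
# disagree for several species (e.g. Acer rubrum 196 vs 201, Taxodium
# distichum 6 vs 12, Fagus grandifolia 21 vs 25); both are recorded here
# verbatim and deliberately NOT reconciled. Empty SD fields correspond to
# species with a single sampled tree.
species,species_code,n_attr,n_cv,dbh_mean_cm,dbh_sd_cm,lcr_mean,lcr_sd
Abies balsamea,12,50,50,17.47,8.79,0.62,0.19
Abies concolor,15,36,36,29.61,14.4,0.71,0.14
Abies grandis,17,20,20,40.13,20.19,0.79,0.14
Abies lasiocarpa,19,28,28,20.68,8.08,0.88,0.13
Juniperus virginiana,68,2,2,14.22,5.03,0.59,0.04
Larix laricina,71,6,6,16.64,8.53,0.82,0.09
Larix occidentalis,73,24,24,31.86,12.66,0.65,0.11
Picea engelmannii,93,51,51,23.33,12.07,0.86,0.1
Picea glauca,94,2,2,31.24,2.87,0.53,0.1
Pinus contorta,108,61,61,22.7,8.54,0.7,0.19
Pinus echinata,110,63,63,9.93,3.78,0.42,0.12
Pinus elliottii,111,540,540,16.65,8.13,0.36,0.1
Pinus glabra,115,1,1,13.21,,0.56,
Pinus palustris,121,150,151,19.78,12.49,0.46,0.12
Pinus ponderosa,122,135,135,30.93,12.7,0.58,0.14
Pinus resinosa,125,13,13,35.66,20.26,0.63,0.2
Pinus rigida,126,31,31,17.6,11.69,0.6,0.14
Pinus strobus,129,137,137,26.23,18.67,0.56,0.16
Pinus taeda,131,242,242,19.01,11.48,0.42,0.17
Pinus virginiana,132,84,84,11.47,7.75,0.63,0.2
Pseudotsuga menziesii,202,152,152,36.79,20.41,0.64,0.18
Taxodium distichum,221,6,12,16.59,3.25,0.4,0.14
Thuja occidentalis,241,13,13,25.2,14.6,0.74,0.12
Tsuga canadensis,261,82,82,25.68,18.25,0.74,0.1
Tsuga heterophylla,263,22,22,43.53,15.69,0.72,0.19
Acer nigrum,314,4,4,35.31,28.22,0.65,0.15
Acer rubrum,316,196,201,19.3,11.33,0.54,0.15
Acer saccharinum,317,14,14,28.47,10.87,0.55,0.11
Acer saccharum,318,87,87,21.86,17.02,0.61,0.13
Betula alleghaniensis,371,2,2,13.84,0.9,0.77,0.01
Betula papyrifera,375,3,3,18.8,3.91,0.61,0.17
Carpinus caroliniana,391,18,18,10.37,4.04,0.56,0.15
Carya cordiformis,402,6,6,43.35,18.59,0.73,0.11
Carya glabra,403,5,5,10.26,4.47,0.71,0.15
Celtis occidentalis,462,10,10,28.37,16.87,0.64,0.16
Cercis canadensis,471,2,5,4.7,0.9,0.6,0.2
Cornus florida,491,6,8,8.42,2.39,0.49,0.16
Fagus grandifolia,531,21,25,36.44,24.13,0.73,0.14
Fraxinus americana,541,6,6,39.88,26.49,0.5,0.12
Ilex opaca,591,1,1,18.8,,0.48,
Juglans nigra,602,1,1,28.96,,0.63,
Liquidambar styraciflua,611,326,452,22.07,10.98,0.45,0.12
Liriodendron tulipifera,621,110,129,28.68,15.9,0.52,0.13
Magnolia virginiana,653,5,6,22.71,6.69,0.39,0.08
Nyssa sylvatica,693,21,21,26.6,10.89,0.56,0.13
Oxydendrum arboreum,711,8,8,12.19,6.05,0.55,0.09
Platanus occidentalis,731,28,29,31.94,11.18,0.47,0.1
Populus tremuloides,746,80,80,23.96,11.43,0.51,0.16
Prunus serotina,762,20,26,12.92,8.61,0.5,0.16
Quercus alba,802,234,238,24.47,15.23,0.56,0.13
Quercus coccinea,806,76,76,28.77,12.53,0.55,0.11
Quercus falcata,812,42,51,29.05,10.95,0.47,0.12
Quercus laurifolia,820,16,39,20.32,8.05,0.49,0.14
Quercus nigra,827,119,161,22.9,11.47,0.5,0.12
Quercus prinus,832,59,71,27.88,15.79,0.53,0.13
Quercus rubra,833,44,49,31.18,21.47,0.54,0.17
Quercus stellata,835,28,28,25.01,11.7,0.57,0.11
Quercus velutina,837,43,44,27.21,14.78,0.51,0.12
Robinia pseudoacacia,901,18,19,27.81,8.64,0.48,0.15
Sassafras albidum,931,1,3,7.87,,0.26,
Tilia americana,951,17,17,37.04,19.57,0.6,0.12
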