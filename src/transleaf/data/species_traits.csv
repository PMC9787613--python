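# Species functional-trait reference table packaged with transleaf.
# Transcribed from the published summary of tree attributes by species:
# leaf longevity (months), shade tolerance score (1 intolerant - 5 tolerant),
# and published wood specific gravity. Species codes follow the FIA-style
# numeric codes used in the published per-species cross-validation table.
# 61 species: 25 softwoods, 36 hardwoods.
species,species_code,group,leaf_longevity_months,shade_tolerance,sg_published
Abies balsamea,12,softwood,110,5.01,0.33
Abies concolor,15,softwood,90,4.33,0.37
Abies grandis,17,softwood,88.8,4.01,0.35
Abies lasiocarpa,19,softwood,96,4.83,0.31
Juniperus virginiana,68,softwood,36,1.28,0.44
Larix laricina,71,softwood,5.5,0.98,0.49
Larix occidentalis,73,softwood,6,1.35,0.48
Picea engelmannii,93,softwood,90,4.53,0.33
Picea glauca,94,softwood,55,4.15,0.33
Pinus contorta,108,softwood,60,1.73,0.38
Pinus echinata,110,softwood,42,1.86,0.47
Pinus elliottii,111,softwood,24,2.65,0.54
Pinus glabra,115,softwood,30,4.5,0.41
Pinus palustris,121,softwood,32,0.87,0.54
Pinus ponderosa,122,softwood,36,1.64,0.38
Pinus resinosa,125,softwood,36,1.89,0.41
Pinus rigida,126,softwood,33,1.99,0.47
Pinus strobus,129,softwood,30,3.21,0.34
Pinus taeda,131,softwood,21.1,1.99,0.47
Pinus virginiana,132,softwood,42,1.99,0.45
Pseudotsuga menziesii,202,softwood,64.8,2.78,0.43
Taxodium distichum,221,softwood,6.5,2.13,0.42
Thuja occidentalis,241,softwood,55,3.45,0.29
Tsuga canadensis,261,softwood,60,4.83,0.38
Tsuga heterophylla,263,softwood,66,4.96,0.42
Acer nigrum,314,hardwood,5.5,3,0.52
Acer rubrum,316,hardwood,5.6,3.44,0.49
Acer saccharinum,317,hardwood,5.5,3.6,0.44
Acer saccharum,318,hardwood,5.5,4.76,0.56
Betula alleghaniensis,371,hardwood,5.5,3.17,0.55
Betula papyrifera,375,hardwood,5,1.54,0.48
Carpinus caroliniana,391,hardwood,5.5,4.58,0.58
Carya cordiformis,402,hardwood,5.5,2.07,0.6
Carya glabra,403,hardwood,5.5,2.69,0.66
Celtis occidentalis,462,hardwood,5.5,3.17,0.49
Cercis canadensis,471,hardwood,6,3,0.65
Cornus florida,491,hardwood,5.6,4.87,0.64
Fagus grandifolia,531,hardwood,6,4.75,0.56
Fraxinus americana,541,hardwood,5.7,2.46,0.55
Ilex opaca,591,hardwood,42,4.28,0.5
Juglans nigra,602,hardwood,5,1.93,0.51
Liquidambar styraciflua,611,hardwood,6,1.59,0.46
Liriodendron tulipifera,621,hardwood,5.3,2.07,0.35
Magnolia virginiana,653,hardwood,12,3,0.42
Nyssa sylvatica,693,hardwood,5.5,3.52,0.46
Oxydendrum arboreum,711,hardwood,6,2.7,0.5
Platanus occidentalis,731,hardwood,6,2.86,0.42
Populus tremuloides,746,hardwood,4.9,1.21,0.35
Prunus serotina,762,hardwood,5.5,2.46,0.47
Quercus alba,802,hardwood,5.5,2.85,0.63
Quercus coccinea,806,hardwood,5.7,2.07,0.62
Quercus falcata,812,hardwood,8.2,2.5,0.58
Quercus laurifolia,820,hardwood,8.4,3.34,0.58
Quercus nigra,827,hardwood,8.6,2.24,0.63
Quercus prinus,832,hardwood,8.2,2.85,0.57
Quercus rubra,833,hardwood,5.5,2.75,0.56
Quercus stellata,835,hardwood,7.9,2.16,0.66
Quercus velutina,837,hardwood,5.5,2.72,0.56
Robinia pseudoacacia,901,hardwood,4.6,1.72,0.67
Sassafras albidum,931,hardwood,5.5,1.68,0.42
Tilia americana,951,hardwood,5.5,3.98,0.32
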