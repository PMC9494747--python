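category,variable,stage,mean,sd,mean_below_precision,sd_below_precision
SOI,soil type,1,0.01,0.01,False,False
SOI,soil texture,1,0.05,0.04,False,False
SOI,bulk density,1,0.04,0.15,False,False
SOI,SOC stock,1,0.03,0.13,False,False
SOI,SON stock,1,0.02,0.09,False,False
SOI,pH,1,0.02,0.09,False,False
SOI,soil mineral N,1,0.02,0.07,False,False
SOI,"FC, WFPS, and CEC",1,0.04,0.19,False,False
SOI,other soil information,1,0.01,0.06,False,False
CL,air temperature,1,0.03,0.03,False,False
CL,precipitation,1,0.04,0.03,False,False
CL,solar radiation,1,0.03,0.01,False,False
CL,air humidity,1,0.01,0.01,False,False
CL,atm. pressure,1,0.01,0.00,False,True
CL,other climate factors,1,0.01,0.00,False,True
MPDE,crop residues,1,0.02,0.01,False,False
MPDE,fertilization rates,1,0.06,0.03,False,False
MPDE,fertilization mode,1,0.02,0.01,False,False
MPDE,fertilizer type,1,0.03,0.02,False,False
MPDE,irrigation,1,0.05,0.02,False,False
MPDE,frequency of plowing,1,0.02,0.01,False,False
MPDE,frequency other activities,1,0.02,0.01,False,False
MPDE,intercropping,1,0.02,0.01,False,False
MPDE,"freq. harvest, grazing, and cut in grass",1,0.03,0.01,False,False
SI,crop type,1,0.02,0.01,False,False
SI,location,1,0.01,0.01,False,False
SI,terrain info,1,0.00,0.00,True,True
SI,experimental length,1,0.01,0.02,False,False
SI,mean regional yield,2,0.01,0.01,False,False
LTCL,air temperature,2,0.01,0.00,False,True
LTCL,precipitation,2,0.01,0.01,False,False
LTCL,solar radiation,2,0.01,0.01,False,False
LTCL,air humidity,2,0.00,0.00,True,True
LTCL,atm. pressure,2,0.00,0.00,True,True
LTCL,other climate factors,2,0.00,0.00,True,True
LTMP,fertilization rates,2,0.01,0.01,False,False
LTMP,fertilization mode,2,0.00,0.00,True,True
LTMP,fertilizer type,2,0.00,0.00,True,True
LTMP,irrigation,2,0.01,0.01,False,False
LTMP,frequency of harvest,2,0.01,0.01,False,False
LTMP,frequency of plowing,2,0.01,0.00,False,True
LTMP,frequency other activities,2,0.00,0.00,True,True
LTMP,crop residues,2,0.01,0.00,False,True
LTMP,intercropping,2,0.01,0.00,False,True
LTMP,land use history,2,0.01,0.01,False,False
EDS,annual extracted yield,3,0.03,0.03,False,False
EDS,"vegetation data (phenology, LAI)",3,0.03,0.03,False,False
EDS,soil temperature,4,0.01,0.01,False,False
EDS,soil moisture,4,0.03,0.01,False,False
EDS,soil mineral N,4,0.02,0.01,False,False
EDS,SOC and SON,5,0.02,0.01,False,False
EDS,GPP and NEP,5,0.02,0.02,False,False
EDS,NEE and Reco,5,0.02,0.02,False,False
EDS,soil N losses,5,0.02,0.01,False,False
EDS,N2O and/or CH4,5,0.03,0.03,False,False
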