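group_code,iso2
OECD,AU
OECD,AT
OECD,BE
OECD,CA
OECD,CL
OECD,CO
OECD,CR
OECD,CZ
OECD,DK
OECD,EE
OECD,FI
OECD,FR
OECD,DE
OECD,GR
OECD,HU
OECD,IS
OECD,IE
OECD,IL
OECD,IT
OECD,JP
OECD,KR
OECD,LV
OECD,LT
OECD,LU
OECD,MX
OECD,NL
OECD,NZ
OECD,NO
OECD,PL
OECD,PT
OECD,SK
OECD,SI
OECD,ES
OECD,SE
OECD,CH
OECD,TR
OECD,GB
OECD,US
BRICS,BR
BRICS,RU
BRICS,IN
BRICS,CN
BRICS,ZA
G77,AF
G77,DZ
G77,AO
G77,AG
G77,AR
G77,AZ
G77,BS
G77,BH
G77,BD
G77,BB
G77,BZ
G77,BJ
G77,BT
G77,BO
G77,BW
G77,BR
G77,BN
G77,BF
G77,BI
G77,CV
G77,KH
G77,CM
G77,CF
G77,TD
G77,CL
G77,CO
G77,KM
G77,CG
G77,CR
G77,CI
G77,CU
G77,KP
G77,CD
G77,DJ
G77,DM
G77,DO
G77,EC
G77,EG
G77,SV
G77,GQ
G77,ER
G77,SZ
G77,ET
G77,FJ
G77,GA
G77,GM
G77,GH
G77,GD
G77,GT
G77,GN
G77,GW
G77,GY
G77,HT
G77,HN
G77,IN
G77,ID
G77,IR
G77,IQ
G77,JM
G77,JO
G77,KE
G77,KI
G77,KW
G77,LA
G77,LB
G77,LS
G77,LR
G77,LY
G77,MG
G77,MW
G77,MY
G77,MV
G77,ML
G77,MH
G77,MR
G77,MU
G77,FM
G77,MN
G77,MA
G77,MZ
G77,MM
G77,NA
G77,NR
G77,NP
G77,NI
G77,NE
G77,NG
G77,OM
G77,PK
G77,PA
G77,PG
G77,PY
G77,PE
G77,PH
G77,QA
G77,RW
G77,KN
G77,LC
G77,VC
G77,WS
G77,ST
G77,SA
G77,SN
G77,SC
G77,SL
G77,SG
G77,SB
G77,SO
G77,ZA
G77,SS
G77,LK
G77,SD
G77,SR
G77,SY
G77,TJ
G77,TZ
G77,TH
G77,TL
G77,TG
G77,TO
G77,TT
G77,TN
G77,TM
G77,TV
G77,UG
G77,AE
G77,UY
G77,VU
G77,VE
G77,VN
G77,YE
G77,ZM
G77,ZW
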