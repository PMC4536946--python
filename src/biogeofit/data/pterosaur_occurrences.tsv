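stage	area	content
Car	North America	Eud
Nor	Europe	Aus
Nor	Europe	Eud
Nor	Europe	Pre
Nor	Europe	Pte
Nor	Europe	Pti
Rha	Europe	Pti
Het	Europe	Dmp
Het	Europe	Pti
Sin	Australia	Dmp
Sin	Europe	Dmp
Sin	North America	Pti
Pli	Africa	Pti
Pli	India	Pti
Pli	North America	Pti
Toa	Europe	Cmp
Toa	Europe	Dmp
Toa	Europe	Rhm
Aal	East Asia	Pti
Aal	North America	Pti
Baj	Central Asia	Rhm
Baj	East Asia	Rhm
Bat	Africa	Pti
Bat	Central Asia	Pti
Bat	East Asia	Anu
Bat	East Asia	Pto
Bat	East Asia	Rhm
Bat	Europe	Pti
Bat	Europe	Rhm
Bat	India	Pti
Bat	North America	Pti
Cal	Central Asia	Rhm
Cal	East Asia	Anu
Cal	Europe	Pti
Cal	Europe	Rhm
Cal	North America	Pti
Cal	South America	Rhm
Oxf	Central Asia	Anu
Oxf	Central Asia	Pdi
Oxf	Central Asia	Rhm
Oxf	Central Asia	Sor
Oxf	East Asia	Rhm
Oxf	East Asia	Wuk
Oxf	Europe	Pti
Oxf	North America	Rhm
Kim	Africa	Ctn
Kim	Africa	Pdi
Kim	Africa	Pti
Kim	Africa	Ten
Kim	Europe	Ard
Kim	Europe	Gal
Kim	Europe	Ger
Kim	Europe	Pti
Kim	Europe	Ptl
Kim	Europe	Rhm
Kim	North America	Ctn
Kim	North America	Pdi
Kim	North America	Pti
Kim	North America	Rhm
Tth	East Asia	Pti
Tth	Europe	Anu
Tth	Europe	Ctn
Tth	Europe	Gal
Tth	Europe	Ger
Tth	Europe	Pdi
Tth	Europe	Pti
Tth	Europe	Ptr
Tth	Europe	Rhm
Tth	South America	Pdi
Ber	Africa	Ctn
Ber	Africa	Pti
Ber	East Asia	Ctn
Ber	East Asia	Dsg
Ber	East Asia	Pti
Ber	Europe	AZH
Ber	Europe	Ctn
Ber	Europe	Lnc
Ber	Europe	Orc
Ber	Europe	Pdi
Ber	Europe	Pti
Ber	South America	Ctn
Ber	South America	Dsg
Val	East Asia	Ctn
Val	East Asia	Orc
Val	East Asia	Pdi
Val	East Asia	Pti
Val	Europe	Orc
Hau	Central Asia	Orc
Hau	East Asia	Pti
Hau	Europe	Orc
Hau	Europe	PTN
Hau	Europe	Pti
Hau	South America	Pdi
Bar	Central Asia	Orc
Bar	East Asia	Anu
Bar	East Asia	Ctn
Bar	East Asia	Hao
Bar	East Asia	Orc
Bar	East Asia	Tpj
Bar	Europe	Isd
Bar	Europe	Orc
Bar	Europe	Pdi
Bar	Europe	Pti
Bar	Europe	Tpj
Bar	South America	Anh
Apt	Africa	AZH
Apt	Africa	PTN
Apt	Central Asia	Orc
Apt	East Asia	Anh
Apt	East Asia	Chy
Apt	East Asia	Ctn
Apt	East Asia	Dsg
Apt	East Asia	Isd
Apt	East Asia	Orc
Apt	East Asia	PTN
Apt	East Asia	Tpj
Apt	Europe	PTN
Apt	Europe	Pti
Apt	North America	Azh
Apt	North America	PTN
Apt	North America	Pdi
Apt	North America	Pti
Apt	South America	AZH
Apt	South America	Anh
Apt	South America	Ctn
Apt	South America	Orc
Apt	South America	Pti
Apt	South America	Tpj
Alb	Africa	Orc
Alb	Australia	Orc
Alb	Australia	Pti
Alb	Central Asia	Pdi
Alb	East Asia	PTN
Alb	Europe	Anh
Alb	Europe	Azh
Alb	Europe	Lnc
Alb	Europe	Orc
Alb	Europe	Pti
Alb	North America	AZH
Alb	North America	Azh
Alb	South America	Anh
Alb	South America	Ctn
Alb	South America	Orc
Alb	South America	PTN
Alb	South America	Pti
Alb	South America	Tpj
Cen	Africa	Anh
Cen	Africa	Azh
Cen	Africa	Orc
Cen	Africa	Pdi
Cen	Africa	Tpj
Cen	Central Asia	Azh
Cen	Central Asia	Orc
Cen	Central Asia	PTN
Cen	Central Asia	Pdi
Cen	East Asia	Azh
Cen	East Asia	Pdi
Cen	Europe	Anh
Cen	Europe	Lnc
Cen	Europe	Orc
Cen	Europe	Pti
Cen	North America	Pti
Cen	North America	Ptn
Cen	South America	AZH
Tur	Central Asia	Azh
Tur	Europe	Pdi
Tur	North America	PTN
Tur	South America	Pdi
Con	Europe	AZH
Con	North America	Nyc
Con	North America	Ptn
San	Central Asia	Azh
San	Central Asia	Pti
San	East Asia	Azh
San	East Asia	Pti
San	Europe	Azh
San	Europe	Tpj
San	North America	Nyc
San	North America	Pti
San	North America	Ptn
Cam	Africa	Azh
Cam	Africa	Pti
Cam	Australia	Pdi
Cam	Central Asia	Azh
Cam	Central Asia	PTN
Cam	East Asia	Azh
Cam	East Asia	Pdi
Cam	Europe	Azh
Cam	Europe	Pdi
Cam	Europe	Pti
Cam	North America	Azh
Cam	North America	Nyc
Cam	North America	Pdi
Cam	North America	Pti
Cam	North America	Ptn
Cam	South America	Azh
Maa	Africa	Azh
Maa	Antarctica	Pdi
Maa	Central Asia	Azh
Maa	Europe	Azh
Maa	Europe	Pti
Maa	India	Pti
Maa	North America	Azh
Maa	North America	Pti
Maa	South America	Nyc
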