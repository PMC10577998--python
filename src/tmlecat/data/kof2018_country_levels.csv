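country,level
Bahamas,Low
Belize,Low
Brazil,Low
Brunei Darussalam,Low
China,Low
Colombia,Low
Cuba,Low
Ecuador,Low
Guatemala,Low
Guyana,Low
Jamaica,Low
Kazakhstan,Low
Kyrgyzstan,Low
Nicaragua,Low
Paraguay,Low
Sri Lanka,Low
Suriname,Low
Syrian Arab Republic,Low
Tajikistan,Low
Trinidad and Tobago,Low
Turkmenistan,Low
Uzbekistan,Low
Venezuela (Bolivarian Republic of),Low
Albania,Mid-Low
Argentina,Mid-Low
Armenia,Mid-Low
Azerbaijan,Mid-Low
Bahrain,Mid-Low
Belarus,Mid-Low
Costa Rica,Mid-Low
Dominican Republic,Mid-Low
El Salvador,Mid-Low
Georgia,Mid-Low
Iceland,Mid-Low
Kuwait,Mid-Low
Mauritius,Mid-Low
Mexico,Mid-Low
North Macedonia,Mid-Low
Panama,Mid-Low
Peru,Mid-Low
Philippines,Mid-Low
Republic of Moldova,Mid-Low
Russian Federation,Mid-Low
South Africa,Mid-Low
Thailand,Mid-Low
Turkey,Mid-Low
Australia,Mid-High
Bulgaria,Mid-High
Chile,Mid-High
Croatia,Mid-High
Israel,Mid-High
Japan,Mid-High
Latvia,Mid-High
Lithuania,Mid-High
Malta,Mid-High
New Zealand,Mid-High
Poland,Mid-High
Republic of Korea,Mid-High
Romania,Mid-High
Serbia,Mid-High
Slovakia,Mid-High
Slovenia,Mid-High
Ukraine,Mid-High
United States of America,Mid-High
Uruguay,Mid-High
Austria,High
Belgium,High
Canada,High
Czechia,High
Denmark,High
Estonia,High
Finland,High
France,High
Germany,High
Greece,High
Hungary,High
Ireland,High
Italy,High
Luxembourg,High
Netherlands,High
Norway,High
Portugal,High
Singapore,High
Spain,High
Sweden,High
Switzerland,High
United Kingdom,High
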