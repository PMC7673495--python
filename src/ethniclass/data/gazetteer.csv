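province,district
Quebec,L'Assomption
Quebec,Montreal
Quebec,Quebec Centre
Quebec,Trois-Rivieres
Quebec,Gaspe
Quebec,Charlevoix
Ontario,York
Ontario,Carleton
Ontario,Wentworth
Ontario,Essex
Ontario,Algoma
Ontario,Nipissing
Nova Scotia,Halifax
Nova Scotia,Cape Breton
Nova Scotia,Pictou
New Brunswick,Saint John
New Brunswick,Northumberland
New Brunswick,Gloucester
Manitoba,Winnipeg
Manitoba,Selkirk
Manitoba,Brandon
British Columbia,Vancouver
British Columbia,Victoria
British Columbia,Yale and Cariboo
British Columbia,Burrard
Prince Edward Island,Queens
Prince Edward Island,Kings
The Territories,Alberta
The Territories,Assiniboia East
The Territories,Assiniboia West
The Territories,Saskatchewan
The Territories,Yukon
The Territories,Mackenzie
The Territories,Keewatin
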